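"""Pipeline orchestration: configuration, stages, and the combined report.

A :class:`RunConfig` names the input files and thresholds; the pipeline
runs the requested stages in dependency order, writes per-stage
TSV/BED/VCF artifacts, and aggregates one machine-readable JSON summary
(counts of calls, events and anomaly regions per type) plus a plain
text report.  Every output carries the config hash in a header comment,
and two runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from . import io as gio
from . import organelle as org
from . import snp as gsnp
from . import tandem_repeats as tr
from .core import WindowGrid
from .mapping import GenotypeMatrix, assign_paternity, family_summary, four_step_filter, read_marker_tsv

logger = logging.getLogger(__name__)

ALL_STAGES = ("repeats", "organelle", "classify-snps", "windows", "segfilter", "paternity")

_KNOWN_KEYS = {
    "inputs", "stages", "window_size", "seed", "out_dir", "log_level", "thresholds",
}
_KNOWN_INPUTS = {
    "genome", "hits_cp", "hits_mt", "pileup", "consensus", "genes",
    "repeats_bed", "trf_dat", "genotypes", "markers",
}
_DEFAULT_THRESHOLDS: Dict[str, Any] = {
    # organelle integration
    "min_identity": 95.0, "min_length": 100, "max_evalue": 1e-10, "max_gap": 0,
    "tiers": [100, 1_000, 5_000, 10_000], "end_distance": 500_000,
    "hotspot_min_span": 1_000_000, "hotspot_min_coverage": 0.5,
    "tandem_neighborhood": 200_000, "tandem_min_events": 3, "tandem_min_source_overlap": 0.5,
    # repeats
    "telomere_family": tr.TELOMERE_FAMILY, "end_zone": 100_000, "min_array_bp": 1_000,
    "centromere_lengths": [79, 80], "cluster_window": 1_000_000,
    # SNPs
    "min_depth": 10, "gap_flank": 3, "ratio_mode": "alt_fraction", "genic_mode": "gene",
    "low_het_min_span": 1_000_000, "het_quantile": 0.1, "flag_span": 5_000_000,
    "repeat_threshold": 0.7, "window_fraction": 0.9, "repeat_min_span": 5_000_000,
    "dup_fraction": 0.2, "dup_min_span": 1_000_000,
    # segregation / paternity
    "seg_min_depth": 20, "min_het_fraction": 0.5, "chi_sq_max": 6.635,
    "max_mismatch": 0, "allow_self": True,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    inputs: Dict[str, str]
    out_dir: str
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    window_size: int = 100_000
    seed: int = 0
    log_level: str = "INFO"
    thresholds: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _KNOWN_INPUTS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown_thr = set(self.thresholds) - set(_DEFAULT_THRESHOLDS)
        if unknown_thr:
            raise ValueError(f"unknown threshold keys: {sorted(unknown_thr)}")
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        merged = dict(_DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "inputs": self.inputs, "stages": self.stages,
                "window_size": self.window_size, "seed": self.seed,
                "thresholds": {k: self.thresholds[k] for k in sorted(self.thresholds)},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute the requested stages and write the report bundle.

    Returns the JSON summary dict.  Missing inputs raise with the file
    named; a failing stage is logged and recorded under ``errors`` while
    outputs of other stages are preserved.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    chash = config.config_hash()
    provenance = [f"config_hash={chash}"]
    for key, value in sorted(thr.items()):
        logger.info("threshold %s = %r", key, value)

    for key, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} not found: {path}")

    summary: Dict[str, Any] = {"config_hash": chash, "errors": []}
    genome = None
    grid: Optional[WindowGrid] = None
    if "genome" in config.inputs:
        genome = gio.read_fasta(config.inputs["genome"])
        grid = WindowGrid.from_genome(genome, config.window_size)
    genes = gio.read_genes_gff3(config.inputs["genes"]) if "genes" in config.inputs else []

    def _stage(name: str):
        def wrap(fn):
            if name not in config.stages:
                return
            try:
                fn()
            except Exception as exc:  # preserve partial outputs
                logger.error("stage %s failed: %s", name, exc)
                summary["errors"].append({"stage": name, "error": str(exc)})
        return wrap

    calls = []
    inter = []

    @_stage("repeats")
    def _repeats():
        records = tr.parse_trf_dat(config.inputs["trf_dat"])
        monomers = tr.merge_monomer_frequencies(records)
        with open(out / "canonical_monomers.tsv", "w") as fh:
            for c in provenance:
                fh.write(f"#{c}\n")
            fh.write("#canonical\tlength\ttotal_frequency\tn_members\n")
            for m in monomers:
                fh.write(f"{m.canonical}\t{m.length}\t{m.total_frequency:.1f}\t{len(m.members)}\n")
        telomeres = tr.call_telomeres(
            genome, records, motif_family=thr["telomere_family"],
            end_zone=thr["end_zone"], min_array_bp=thr["min_array_bp"],
        )
        centromeres = tr.call_centromeres(
            records, monomer_lengths=set(thr["centromere_lengths"]),
            cluster_window=thr["cluster_window"], chromosomes=genome.chromosomes,
        )
        regions = [
            (t.array_span, f"telomere_{t.end}") for t in telomeres if t.present
        ] + [
            (c.main_cluster, "centromere") for c in centromeres if c.main_cluster
        ]
        gio.write_regions_bed(regions, out / "telomere_centromere.bed", provenance)
        summary["repeats"] = {
            "canonical_monomers": len(monomers),
            "top_family": monomers[0].canonical if monomers else None,
            "top_family_frequency": monomers[0].total_frequency if monomers else 0,
            "telomere_ends_present": sum(t.present for t in telomeres),
            "telomeres": [
                {"chrom": t.chrom, "end": t.end, "array_bp": t.array_bp}
                for t in telomeres if t.present
            ],
            "centromere_clusters": sum(1 for c in centromeres if c.main_cluster),
        }

    @_stage("organelle")
    def _organelle():
        events = {}
        anomalies = []
        for organelle in ("cp", "mt"):
            key = f"hits_{organelle}"
            if key not in config.inputs:
                continue
            hits = org.filter_hits(
                gio.read_hits_tabular(config.inputs[key]),
                min_identity=thr["min_identity"], min_length=thr["min_length"],
                max_evalue=thr["max_evalue"],
            )
            events[organelle] = org.merge_hits_to_events(
                hits, organelle=organelle, max_gap=thr["max_gap"]
            )
        pooled = [e for evs in events.values() for e in evs]
        profile = org.count_events_per_window(pooled, grid, tiers=thr["tiers"])
        gio.write_profile_tsv(profile.counts, out / "insertion_windows.tsv", provenance)
        anomalies += org.detect_end_proximal(pooled, genome, thr["end_distance"])
        anomalies += org.detect_co_localization(
            events.get("cp", []), events.get("mt", []), grid, thr["end_distance"]
        )
        anomalies += org.detect_hotspot(
            pooled, grid, thr["hotspot_min_span"], thr["hotspot_min_coverage"]
        )
        for organelle, evs in events.items():
            anomalies += org.detect_tandem_like(
                evs, thr["tandem_neighborhood"], thr["tandem_min_events"],
                thr["tandem_min_source_overlap"],
            )
        gio.write_regions_bed(
            [(a.interval, a.type) for a in anomalies], out / "organelle_anomalies.bed",
            provenance,
        )
        by_type: Dict[str, int] = {}
        for a in anomalies:
            by_type[a.type] = by_type.get(a.type, 0) + 1
        summary["organelle"] = {
            "events": {o: len(evs) for o, evs in events.items()},
            "events_ge10kb": {
                o: sum(1 for e in evs if e.length >= 10_000) for o, evs in events.items()
            },
            "anomalies": by_type,
        }

    @_stage("classify-snps")
    def _snps():
        nonlocal calls, inter
        sites = gio.read_pileup_tsv(config.inputs["pileup"])
        calls = gsnp.classify_pileup(
            sites, genome.gaps, min_depth=thr["min_depth"],
            gap_flank=thr["gap_flank"], ratio_mode=thr["ratio_mode"],
        )
        if "consensus" in config.inputs:
            consensus = gio.read_consensus_tsv(config.inputs["consensus"])
            inter = gsnp.call_inter_individual(calls, consensus)
        gio.write_snp_vcf(calls, out / "snp_calls.vcf", sample="indivA",
                          header_comments=provenance)
        states: Dict[str, int] = {}
        for c in calls:
            states[c.state] = states.get(c.state, 0) + 1
        summary["snp"] = {
            "n_sites": len(calls), "states": states,
            "inter_individual_hom_diff": len(inter),
        }

    @_stage("windows")
    def _windows():
        profile = gsnp.profile_snp_windows(calls, inter, genes, grid,
                                           genic_mode=thr["genic_mode"])
        gio.write_profile_tsv(profile.table, out / "snp_windows.tsv", provenance)
        anomalies = gsnp.detect_low_het_regions(
            profile, thr["low_het_min_span"], thr["het_quantile"], thr["flag_span"]
        )
        anomalies += gsnp.detect_decoupled_windows(profile)
        if "repeats_bed" in config.inputs:
            repeat_iv = [iv for iv, _ in gio.read_regions_bed(config.inputs["repeats_bed"])]
            rprofile = gsnp.repeat_fraction_profile(repeat_iv, grid)
            gio.write_profile_tsv(rprofile, out / "repeat_windows.tsv", provenance)
            anomalies += gsnp.detect_repeat_gene_anomalies(
                rprofile, genes, grid, thr["repeat_threshold"], thr["window_fraction"],
                thr["repeat_min_span"], thr["dup_fraction"], thr["dup_min_span"],
            )
        gio.write_regions_bed(
            [(a.interval, a.type + ("_extended" if a.extended else "")) for a in anomalies],
            out / "landscape_anomalies.bed", provenance,
        )
        hist = gsnp.window_count_histogram(profile)
        gio.write_profile_tsv(hist, out / "snp_window_histogram.tsv", provenance)
        by_type: Dict[str, int] = {}
        for a in anomalies:
            by_type[a.type] = by_type.get(a.type, 0) + 1
        summary["windows"] = {
            "n_windows": grid.n_windows(),
            "anomalies": by_type,
            "extended_low_het": sum(1 for a in anomalies
                                    if a.type in ("low_het", "low_both") and a.extended),
        }

    @_stage("segfilter")
    def _segfilter():
        matrix = GenotypeMatrix.from_tsv(config.inputs["genotypes"])
        result = four_step_filter(
            matrix, min_depth=thr["seg_min_depth"],
            min_het_fraction=thr["min_het_fraction"], chi_sq_max=thr["chi_sq_max"],
        )
        with open(out / "retained_loci.tsv", "w") as fh:
            for c in provenance:
                fh.write(f"#{c}\n")
            fh.write("#locus\tcontig\tposition\tchi_square\n")
            for locus in result.retained_loci:
                fh.write(
                    f"{locus}\t{matrix.loci.at[locus, 'contig']}\t"
                    f"{int(matrix.loci.at[locus, 'position'])}\t"
                    f"{result.chi_square.get(locus, float('nan')):.4f}\n"
                )
        summary["segregation"] = {
            "per_step_counts": list(result.per_step_counts),
            "retained": len(result.retained_loci),
        }

    @_stage("paternity")
    def _paternity():
        panel, roles = read_marker_tsv(config.inputs["markers"])
        mother = next(p for p in panel if roles[p.individual] == "mother")
        cands = [p for p in panel if roles[p.individual] in ("mother", "candidate")]
        offspring = [p for p in panel if roles[p.individual] == "offspring"]
        assignments = assign_paternity(
            offspring, mother, cands,
            max_mismatch=thr["max_mismatch"], allow_self=thr["allow_self"],
        )
        with open(out / "paternity.tsv", "w") as fh:
            for c in provenance:
                fh.write(f"#{c}\n")
            fh.write("#offspring\tstatus\tfather\tmin_mismatches\n")
            for a in assignments:
                mn = min(a.mismatch_counts.values()) if a.mismatch_counts else -1
                fh.write(f"{a.offspring}\t{a.status}\t{a.assigned_father or '-'}\t{mn}\n")
        families, total = family_summary(assignments)
        summary["paternity"] = {
            "assigned": sum(1 for a in assignments if a.status == "assigned"),
            "ambiguous": sum(1 for a in assignments if a.status == "ambiguous"),
            "unassigned": sum(1 for a in assignments if a.status == "unassigned"),
            "families": {k: int(v) for k, v in families.items()},
            "family_total": total,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_text_report(summary, out / "report.txt", chash)
    return summary


def _write_text_report(summary: Dict[str, Any], path, chash: str) -> None:
    lines = [f"genarch pipeline report (config {chash})", "=" * 44]
    for section in sorted(summary):
        if section in ("config_hash",):
            continue
        lines.append(f"[{section}]")
        lines.append(json.dumps(summary[section], indent=2, sort_keys=True))
        lines.append("")
    Path(path).write_text("\n".join(lines))
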
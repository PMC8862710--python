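"""Seeded synthetic genomes with planted ground truth.

The generator emits a toy multi-chromosome assembly carrying every
structure the analysis modules look for — telomeric TTTAGGG arrays,
79/80 bp centromeric satellite clusters with scattered copies, organelle
fragments inserted at 95-100% identity in tiered lengths (including a
multi-Mb integration hotspot and a tandem-like cluster re-using one
chloroplast span), SNP sites of known state with a multi-Mb
low-heterozygosity stretch, repeat-rich and duplicated-gene anomaly
regions, a half-sib genotype matrix segregating 1:1 with planted
distorted loci, and a paternity marker panel with known fathers — plus
a machine-readable truth table.  Alignment hits are synthesized from
the planted insertions (coordinates plus the substitutions applied to
reach the target identity), so no external aligner is needed and the
generator/analyzer pair forms a closed parameter-recovery loop.

Background sequence is i.i.d. uniform ACGT, which maximizes the
contrast of planted features; one seed fixes every draw, and repeated
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval, WindowGrid, reverse_complement
from .io import (
    write_consensus_tsv,
    write_fasta,
    write_genes_gff3,
    write_pileup_tsv,
    write_regions_bed,
)
from .core import GeneModel, PileupSite
from .mapping import GenotypeMatrix, MarkerGenotypes, write_marker_tsv
from .organelle import tiers_for_length
from .tandem_repeats import TandemRecord, write_trf_dat

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Plans


@dataclass
class TelomerePlan:
    chrom: str
    end: str  # "left" | "right"
    array_bp: int = 12_000
    motif: str = "TTTAGGG"


@dataclass
class CentromerePlan:
    chrom: str
    cluster_start: int
    monomer_length: int = 79  # 79 or 80 bp satellite families
    cluster_copies: int = 500
    scattered: Tuple[Tuple[int, int], ...] = ()  # (start, copies) loci


@dataclass
class InsertionPlan:
    organelle: str  # "cp" | "mt"
    chrom: str
    target_start: int
    length: int
    identity: float
    source_start: int
    strand: str = "+"


@dataclass
class GapPlan:
    chrom: str
    start: int
    length: int = 100


@dataclass
class SnpPlan:
    het_per_window: float = 50.0
    hom_per_window: float = 25.0
    depth_mean: float = 30.0
    noiseless: bool = False  # fixed depth, exactly balanced het alleles
    low_het_regions: Tuple[Tuple[str, int, int, float, float], ...] = ()
    # (chrom, start, end, het_per_window, hom_per_window)
    hom_alt_sites_per_chrom: int = 2
    low_depth_sites_per_chrom: int = 2


@dataclass
class RepeatPlan:
    background_fraction: float = 0.3
    rich_regions: Tuple[Tuple[str, int, int, float], ...] = ()  # chrom,start,end,fraction
    dip_every: int = 21  # every Nth region window dips to 0.5 (keeps ~97% above)


@dataclass
class GenePlan:
    spacing: int = 20_000
    length: int = 3_000
    background_dup_every: int = 20  # 5% duplication-flagged background
    dup_clusters: Tuple[Tuple[str, int, int], ...] = ()  # 40% flagged inside


@dataclass
class MappingPlan:
    n_offspring: int = 200
    n_contigs: int = 40
    # planted het counts out of n_offspring per locus class
    class_het_counts: Tuple[Tuple[str, int], ...] = (
        ("1:1", 100),
        ("distorted", 130),
        ("under_het", 80),
    )
    error_rate: float = 0.0
    missing_rate: float = 0.0
    depth_floor: int = 20
    depth_extra_mean: float = 20.0  # depth = floor + Poisson(extra)


@dataclass
class PaternityPlan:
    n_candidates: int = 19  # plus the mother herself (selfing)
    n_loci: int = 36
    n_mother_het: int = 12
    n_offspring: int = 50
    error_rate: float = 0.0
    missing_rate: float = 0.0245  # ~ proportion of loci untyped
    min_pairwise_separation: int = 2


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic dataset; ``seed`` fixes every draw."""

    seed: int
    chrom_lengths: Dict[str, int]
    organelle_lengths: Dict[str, int] = field(
        default_factory=lambda: {"cp": 160_000, "mt": 504_000}
    )
    telomeres: Tuple[TelomerePlan, ...] = ()
    centromeres: Tuple[CentromerePlan, ...] = ()
    insertions: Tuple[InsertionPlan, ...] = ()
    gaps: Tuple[GapPlan, ...] = ()
    snp: SnpPlan = field(default_factory=SnpPlan)
    repeats: RepeatPlan = field(default_factory=RepeatPlan)
    genes: GenePlan = field(default_factory=GenePlan)
    mapping: MappingPlan = field(default_factory=MappingPlan)
    paternity: PaternityPlan = field(default_factory=PaternityPlan)
    window_size: int = 100_000
    noise_hits: bool = True  # sub-threshold alignment hits to exercise filtering

    # ------------------------------------------------------------------
    @classmethod
    def default(cls, seed: int, noiseless_snps: bool = False) -> "SimulationConfig":
        """The standard study-condition layout on a 42 Mb toy genome.

        Three chromosomes carry, between them, telomeres at five of six
        ends, one centromere cluster each (79/80 bp families), tiered
        cp/mt insertions including end-proximal and co-localized cases,
        a tandem-like chloroplast cluster, a 2 Mb integration hotspot at
        0.6 event coverage, a 6 Mb heterozygosity desert with elevated
        homozygous differences, a 6 Mb repeat-rich region and a
        duplicated-gene cluster.
        """
        lengths = {"chr1": 16_000_000, "chr2": 16_000_000, "chr3": 10_000_000}
        telomeres = (
            TelomerePlan("chr1", "left"),
            TelomerePlan("chr1", "right"),
            TelomerePlan("chr2", "left"),
            TelomerePlan("chr2", "right"),
            TelomerePlan("chr3", "left"),
        )
        centromeres = (
            CentromerePlan(
                "chr1", 7_000_000, 79, 500,
                scattered=((1_200_000, 4), (3_900_000, 4), (10_500_000, 4),
                           (12_800_000, 4), (14_200_000, 4)),
            ),
            CentromerePlan(
                "chr2", 8_000_000, 80, 500,
                scattered=((900_000, 5), (5_900_000, 5), (9_500_000, 5), (13_500_000, 5)),
            ),
            CentromerePlan("chr3", 4_500_000, 79, 500,
                           scattered=((1_000_000, 4), (9_000_000, 4))),
        )
        insertions: List[InsertionPlan] = [
            # tandem-like cluster on chr1: three events re-using one cp span
            InsertionPlan("cp", "chr1", 5_000_000, 8_000, 99.0, 20_000),
            InsertionPlan("cp", "chr1", 5_060_000, 8_000, 99.0, 20_000),
            InsertionPlan("cp", "chr1", 5_120_000, 8_000, 98.0, 20_000),
            # co-localized cp + mt in one mid-chromosome window on chr1
            InsertionPlan("cp", "chr1", 4_250_000, 2_000, 97.0, 50_000),
            InsertionPlan("mt", "chr1", 4_280_000, 3_000, 96.0, 100_000),
            # end-proximal pair on the chr2 left end
            InsertionPlan("cp", "chr2", 300_000, 1_000, 99.0, 60_000),
            InsertionPlan("mt", "chr2", 400_000, 1_500, 98.0, 150_000),
            # tiered scatter on chr2
            InsertionPlan("cp", "chr2", 1_500_000, 150, 96.0, 1_000),
            InsertionPlan("cp", "chr2", 1_800_000, 800, 98.0, 5_000, strand="-"),
            InsertionPlan("cp", "chr2", 2_200_000, 1_500, 99.0, 10_000),
            InsertionPlan("cp", "chr2", 2_600_000, 6_000, 100.0, 40_000),
            InsertionPlan("cp", "chr2", 3_000_000, 12_000, 95.0, 70_000),
            InsertionPlan("cp", "chr2", 3_400_000, 30_000, 95.0, 90_000),
            InsertionPlan("mt", "chr2", 4_000_000, 200, 98.0, 200_000, strand="-"),
            InsertionPlan("mt", "chr2", 4_300_000, 1_200, 99.0, 250_000),
            InsertionPlan("mt", "chr2", 4_600_000, 12_000, 96.0, 300_000),
        ]
        # 2 Mb hotspot on chr3: one 30 kb cp + one 25 kb mt event per
        # 100 kb window (0.55 coverage); cp spans cycle 5 disjoint spans
        # of the small cp genome, so their re-use is itself tandem-like.
        cp_spans = [0, 32_000, 64_000, 96_000, 128_000]
        identities = [100.0, 99.0, 98.0, 96.5, 96.0]
        for k in range(20):
            w = 6_000_000 + k * 100_000
            insertions.append(
                InsertionPlan("cp", "chr3", w + 5_000, 30_000,
                              identities[k % 5], cp_spans[k % 5])
            )
            insertions.append(
                InsertionPlan("mt", "chr3", w + 40_000, 25_000,
                              identities[(k + 2) % 5], k * 25_200)
            )
        gaps = (
            GapPlan("chr1", 6_000_000, 150),
            GapPlan("chr1", 8_000_000, 100),
            GapPlan("chr2", 5_500_000, 100),
            GapPlan("chr2", 14_000_000, 100),
            GapPlan("chr3", 2_000_000, 100),
        )
        return cls(
            seed=seed,
            chrom_lengths=lengths,
            telomeres=telomeres,
            centromeres=centromeres,
            insertions=tuple(insertions),
            gaps=gaps,
            snp=SnpPlan(
                noiseless=noiseless_snps,
                low_het_regions=(("chr2", 7_000_000, 13_000_000, 0.0, 40.0),),
            ),
            repeats=RepeatPlan(rich_regions=(("chr1", 9_000_000, 15_000_000, 0.75),)),
            genes=GenePlan(dup_clusters=(("chr1", 2_000_000, 3_500_000),)),
        )

    @classmethod
    def feature_free(cls, seed: int) -> "SimulationConfig":
        """A homogeneous genome: no planted features, uniform densities."""
        return cls(
            seed=seed,
            chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000, "chr3": 5_000_000},
            gaps=(GapPlan("chr1", 2_500_000), GapPlan("chr2", 2_500_000),
                  GapPlan("chr3", 2_500_000)),
            noise_hits=False,
        )

    # ------------------------------------------------------------------
    def sequence_features(self) -> List[Tuple[GenomicInterval, str]]:
        """All features written into the sequence, for overlap validation."""
        feats: List[Tuple[GenomicInterval, str]] = []
        for t in self.telomeres:
            L = self.chrom_lengths[t.chrom]
            start = 0 if t.end == "left" else L - t.array_bp
            feats.append((GenomicInterval(t.chrom, start, start + t.array_bp),
                          f"telomere:{t.chrom}:{t.end}"))
        for c in self.centromeres:
            span = c.cluster_copies * c.monomer_length
            feats.append((GenomicInterval(c.chrom, c.cluster_start, c.cluster_start + span),
                          f"centromere:{c.chrom}"))
            for start, copies in c.scattered:
                feats.append((GenomicInterval(c.chrom, start, start + copies * c.monomer_length),
                              f"centromere_scattered:{c.chrom}:{start}"))
        for i in self.insertions:
            feats.append((GenomicInterval(i.chrom, i.target_start, i.target_start + i.length),
                          f"insertion:{i.organelle}:{i.chrom}:{i.target_start}"))
        for g in self.gaps:
            feats.append((GenomicInterval(g.chrom, g.start, g.start + g.length),
                          f"gap:{g.chrom}:{g.start}"))
        return feats

    def validate(self) -> None:
        feats = self.sequence_features()
        for iv, label in feats:
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"{label}: unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(f"{label}: extends beyond chromosome end")
        collisions = []
        by_chrom: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
        for iv, label in feats:
            by_chrom.setdefault(iv.chrom, []).append((iv, label))
        for chrom, items in by_chrom.items():
            items.sort(key=lambda x: x[0].start)
            for (a, la), (b, lb) in zip(items, items[1:]):
                if b.start < a.end:
                    collisions.append(f"{la} overlaps {lb}")
        if collisions:
            raise ValueError("overlapping planted features: " + "; ".join(collisions))


# ---------------------------------------------------------------------------
# Truth table


@dataclass
class TruthTable:
    """Planted ground truth, consistent with the emitted files."""

    telomeres: List[dict] = field(default_factory=list)
    centromeres: List[dict] = field(default_factory=list)
    insertions: List[dict] = field(default_factory=list)
    hotspots: List[dict] = field(default_factory=list)
    tandem_like: List[dict] = field(default_factory=list)
    end_proximal: List[dict] = field(default_factory=list)
    co_localized_windows: List[dict] = field(default_factory=list)
    low_het_regions: List[dict] = field(default_factory=list)
    repeat_rich: List[dict] = field(default_factory=list)
    dup_gene_clusters: List[dict] = field(default_factory=list)
    snp_counts: Dict[str, int] = field(default_factory=dict)
    segregation_classes: Dict[str, str] = field(default_factory=dict)
    planted_1to1: List[str] = field(default_factory=list)
    true_fathers: Dict[str, str] = field(default_factory=dict)
    snp_sites: Optional[pd.DataFrame] = None  # chrom, pos (0-based), true_state

    def to_json(self, path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "snp_sites"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path, sites_path=None) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        tt = cls(**payload)
        if sites_path is not None:
            tt.snp_sites = pd.read_csv(sites_path, sep="\t", comment="#")
        return tt


# ---------------------------------------------------------------------------
# Primitive operations


def random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def mutate_to_identity(fragment: str, identity: float, seed) -> str:
    """Apply ``round((1 - identity/100) * len)`` substitutions to a fragment.

    Substituted positions are distinct, each new base differs from the
    old one, and ``N`` is never introduced.  ``seed`` may be an integer
    or a ``numpy.random.Generator``.
    """
    if not 0.0 < identity <= 100.0:
        raise ValueError(f"identity must be in (0, 100], got {identity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round((1.0 - identity / 100.0) * len(fragment))
    if n_sub > len(fragment):
        raise ValueError(f"{n_sub} substitutions exceed fragment length {len(fragment)}")
    if n_sub == 0:
        return fragment
    positions = rng.choice(len(fragment), size=n_sub, replace=False)
    out = list(fragment)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def achieved_identity(length: int, identity: float) -> float:
    """Identity actually realized after the rounded substitution count."""
    n_sub = round((1.0 - identity / 100.0) * length)
    return 100.0 * (1.0 - n_sub / length)


def _rotate(s: str, k: int) -> str:
    k %= len(s)
    return s[k:] + s[:k]


# ---------------------------------------------------------------------------
# Generator


def simulate(config: SimulationConfig, out_dir) -> Tuple[Dict[str, Path], TruthTable]:
    """Materialize a config: emit all files and return (paths, truth).

    Identical configs (same seed) produce byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    paths: Dict[str, Path] = {}

    # --- organelle genomes -------------------------------------------------
    organelles: Dict[str, str] = {}
    for name, length in config.organelle_lengths.items():
        organelles[name] = random_sequence(rng, length).tobytes().decode()
        paths[f"{name}_fasta"] = out / f"{name}.fa"
        write_fasta({name: organelles[name]}, paths[f"{name}_fasta"])

    # --- nuclear chromosomes ----------------------------------------------
    chrom_arrays: Dict[str, np.ndarray] = {
        chrom: random_sequence(rng, L) for chrom, L in config.chrom_lengths.items()
    }

    def _write(chrom: str, start: int, seq: str) -> None:
        chrom_arrays[chrom][start : start + len(seq)] = np.frombuffer(
            seq.encode(), dtype=np.uint8
        )

    # satellite monomer families, one per monomer length in use
    families: Dict[int, str] = {}
    for c in config.centromeres:
        if c.monomer_length not in families:
            families[c.monomer_length] = (
                random_sequence(rng, c.monomer_length).tobytes().decode()
            )

    trf_records: Dict[str, List[TandemRecord]] = {c: [] for c in config.chrom_lengths}

    for t in config.telomeres:
        L = config.chrom_lengths[t.chrom]
        start = 0 if t.end == "left" else L - t.array_bp
        motif = t.motif
        array = (motif * (t.array_bp // len(motif) + 1))[: t.array_bp]
        _write(t.chrom, start, array)
        # two TRF records per array, phase-shifted / strand-flipped monomers,
        # to exercise canonical merging downstream
        split = (t.array_bp * 3) // 5
        rot1 = _rotate(motif, int(rng.integers(0, len(motif))))
        rot2 = reverse_complement(_rotate(motif, int(rng.integers(0, len(motif)))))
        for s, e, mono in ((start, start + split, rot1), (start + split, start + t.array_bp, rot2)):
            trf_records[t.chrom].append(
                TandemRecord(
                    locus=GenomicInterval(t.chrom, s, e),
                    period=len(motif),
                    copy_number=round((e - s) / len(motif), 1),
                    monomer=mono,
                )
            )
        truth.telomeres.append(
            {"chrom": t.chrom, "end": t.end, "start": start,
             "stop": start + t.array_bp, "array_bp": t.array_bp}
        )

    from .tandem_repeats import canonical_monomer

    for c in config.centromeres:
        mono = families[c.monomer_length]
        span = c.cluster_copies * c.monomer_length
        _write(c.chrom, c.cluster_start, mono * c.cluster_copies)
        half = c.cluster_copies // 2
        parts = (
            (c.cluster_start, half, _rotate(mono, int(rng.integers(0, len(mono))))),
            (c.cluster_start + half * c.monomer_length, c.cluster_copies - half,
             reverse_complement(_rotate(mono, int(rng.integers(0, len(mono)))))),
        )
        for s, copies, variant in parts:
            trf_records[c.chrom].append(
                TandemRecord(
                    locus=GenomicInterval(c.chrom, s, s + copies * c.monomer_length),
                    period=c.monomer_length,
                    copy_number=float(copies),
                    monomer=variant,
                )
            )
        n_scattered = 0
        for start, copies in c.scattered:
            _write(c.chrom, start, mono * copies)
            trf_records[c.chrom].append(
                TandemRecord(
                    locus=GenomicInterval(c.chrom, start, start + copies * c.monomer_length),
                    period=c.monomer_length,
                    copy_number=float(copies),
                    monomer=_rotate(mono, int(rng.integers(0, len(mono)))),
                )
            )
            n_scattered += copies
        truth.centromeres.append(
            {"chrom": c.chrom, "start": c.cluster_start, "stop": c.cluster_start + span,
             "copies": c.cluster_copies, "scattered_copies": n_scattered,
             "monomer_length": c.monomer_length, "family": canonical_monomer(mono)}
        )

    # background tandem records (.dat only; never telomeric or 79/80 bp)
    bg_periods = [2, 5, 21, 150, 301]
    for chrom, L in config.chrom_lengths.items():
        for j, p in enumerate(bg_periods):
            mono = random_sequence(rng, p).tobytes().decode()
            copies = float(rng.integers(3, 20))
            start = int(rng.integers(200_000, L - 300_000))
            trf_records[chrom].append(
                TandemRecord(
                    locus=GenomicInterval(chrom, start, start + int(copies * p)),
                    period=p, copy_number=copies, monomer=mono,
                )
            )

    # --- organelle insertions ----------------------------------------------
    hit_rows: List[str] = []
    for ins in config.insertions:
        fragment = organelles[ins.organelle][ins.source_start : ins.source_start + ins.length]
        if len(fragment) < ins.length:
            raise ValueError(
                f"insertion source span exceeds {ins.organelle} genome "
                f"({ins.source_start}+{ins.length})"
            )
        mutated = mutate_to_identity(fragment, ins.identity, rng)
        n_sub = sum(a != b for a, b in zip(fragment, mutated))
        ident = 100.0 * (1.0 - n_sub / ins.length)
        _write(ins.chrom, ins.target_start,
               reverse_complement(mutated) if ins.strand == "-" else mutated)
        sstart, send = ins.target_start + 1, ins.target_start + ins.length
        if ins.strand == "-":
            sstart, send = send, sstart
        hit_rows.append(
            "\t".join(
                str(x)
                for x in (
                    ins.organelle, ins.chrom, f"{ident:.3f}", ins.length, n_sub, 0,
                    ins.source_start + 1, ins.source_start + ins.length,
                    sstart, send, "1e-50", round(1.8 * ins.length, 1),
                )
            )
        )
        truth.insertions.append(
            {"organelle": ins.organelle, "chrom": ins.chrom,
             "start": ins.target_start, "stop": ins.target_start + ins.length,
             "length": ins.length, "identity": round(ident, 3),
             "tiers": list(tiers_for_length(ins.length)),
             "source_start": ins.source_start,
             "source_stop": ins.source_start + ins.length, "strand": ins.strand}
        )
    if config.noise_hits and config.insertions:
        first_chrom = next(iter(config.chrom_lengths))
        L = config.chrom_lengths[first_chrom]
        for organelle in config.organelle_lengths:
            for ident, length, evalue in (
                (90.0, 500, "1e-40"), (92.5, 2_000, "1e-40"), (94.9, 300, "1e-40"),
                (99.0, 50, "1e-40"), (98.0, 80, "1e-40"), (99.5, 400, "1e-05"),
            ):
                pos = int(rng.integers(500_000, L - 500_000))
                src = int(rng.integers(0, config.organelle_lengths[organelle] - length))
                hit_rows.append(
                    "\t".join(
                        str(x)
                        for x in (
                            organelle, first_chrom, f"{ident:.3f}", length,
                            round(length * (1 - ident / 100)), 0,
                            src + 1, src + length, pos + 1, pos + length,
                            evalue, round(1.8 * length, 1),
                        )
                    )
                )
    for organelle in config.organelle_lengths:
        paths[f"hits_{organelle}"] = out / f"hits_{organelle}.tsv"
        with open(paths[f"hits_{organelle}"], "w") as fh:
            for row in hit_rows:
                if row.startswith(organelle + "\t"):
                    fh.write(row + "\n")

    _derive_organelle_truth(config, truth)

    # --- gaps, genome FASTA -------------------------------------------------
    for g in config.gaps:
        _write(g.chrom, g.start, "N" * g.length)
    sequences = {c: a.tobytes().decode() for c, a in chrom_arrays.items()}
    genome = Genome.from_sequences(sequences)
    paths["genome_fasta"] = out / "genome.fa"
    write_fasta(genome, paths["genome_fasta"])

    paths["trf_dat"] = out / "tandem.dat"
    write_trf_dat(trf_records, paths["trf_dat"])
    # two over-long monomers appended raw: the parser must drop them
    with open(paths["trf_dat"], "a") as fh:
        last_chrom = list(config.chrom_lengths)[-1]
        long_mono = random_sequence(rng, 501).tobytes().decode()
        fh.write(f"Sequence: {last_chrom}\n\n")
        for start in (600_000, 700_000):
            fh.write(
                f"{start + 1} {start + 1503} 501 3.0 501 100 0 3006 "
                f"25 25 25 25 2.0 {long_mono} {long_mono * 3}\n"
            )

    # --- repeat annotation BED ----------------------------------------------
    grid = WindowGrid.from_lengths(config.chrom_lengths, config.window_size)
    repeat_regions: List[Tuple[GenomicInterval, str]] = []
    rich_lookup = {
        chrom: (start, stop, frac)
        for chrom, start, stop, frac in config.repeats.rich_regions
    }
    for chrom, tiles in grid.windows.items():
        rich = rich_lookup.get(chrom)
        region_wi = 0
        for w in tiles:
            frac = config.repeats.background_fraction
            if rich and rich[0] <= w.start and w.end <= rich[1]:
                region_wi += 1
                frac = 0.5 if region_wi % config.repeats.dip_every == 0 else rich[2]
            covered = int(frac * w.length)
            if covered:
                repeat_regions.append(
                    (GenomicInterval(chrom, w.start, w.start + covered), "repeat")
                )
    paths["repeats_bed"] = out / "repeats.bed"
    write_regions_bed(repeat_regions, paths["repeats_bed"])
    for chrom, start, stop, frac in config.repeats.rich_regions:
        truth.repeat_rich.append({"chrom": chrom, "start": start, "stop": stop,
                                  "fraction": frac})

    # --- gene models ---------------------------------------------------------
    gene_models: List[GeneModel] = []
    clusters = {chrom: (s, e) for chrom, s, e in config.genes.dup_clusters}
    gi = 0
    for chrom, L in config.chrom_lengths.items():
        for start in range(5_000, L - config.genes.length - 5_000, config.genes.spacing):
            gi += 1
            in_cluster = chrom in clusters and clusters[chrom][0] <= start < clusters[chrom][1]
            flagged = (gi % 5 < 2) if in_cluster else (gi % config.genes.background_dup_every == 0)
            exon_len = config.genes.length // 3
            gene_models.append(
                GeneModel(
                    interval=GenomicInterval(chrom, start, start + config.genes.length, "+"),
                    id=f"gene{gi:05d}",
                    exons=[
                        GenomicInterval(chrom, start, start + exon_len, "+"),
                        GenomicInterval(chrom, start + 2 * exon_len,
                                        start + config.genes.length, "+"),
                    ],
                    duplication_flag=bool(flagged),
                )
            )
    paths["genes_gff3"] = out / "genes.gff3"
    write_genes_gff3(gene_models, paths["genes_gff3"])
    for chrom, s, e in config.genes.dup_clusters:
        truth.dup_gene_clusters.append({"chrom": chrom, "start": s, "stop": e})

    # --- SNP pileup + second-individual consensus ----------------------------
    sites, consensus, site_truth = _simulate_snps(config, genome, grid, rng)
    paths["pileup"] = out / "pileup.tsv"
    write_pileup_tsv(sites, paths["pileup"])
    paths["consensus"] = out / "consensus_b.tsv"
    write_consensus_tsv(consensus, paths["consensus"])
    truth.snp_sites = site_truth
    truth.snp_counts = {
        str(k): int(v) for k, v in site_truth["true_state"].value_counts().items()
    }
    for chrom, start, stop, het_d, hom_d in config.snp.low_het_regions:
        truth.low_het_regions.append(
            {"chrom": chrom, "start": start, "stop": stop,
             "het_per_window": het_d, "hom_per_window": hom_d,
             "extended": (stop - start) >= 5_000_000}
        )
    paths["truth_sites"] = out / "truth_sites.tsv"
    with open(paths["truth_sites"], "w") as fh:
        fh.write("#0-based positions\n")
        site_truth.to_csv(fh, sep="\t", index=False)

    # --- mapping population ---------------------------------------------------
    matrix, seg_classes, planted = _simulate_mapping(config.mapping, rng)
    paths["genotypes"] = out / "genotypes.tsv"
    matrix.to_tsv(paths["genotypes"])
    truth.segregation_classes = seg_classes
    truth.planted_1to1 = planted

    # --- paternity panel -------------------------------------------------------
    panel, roles, fathers = _simulate_paternity(config.paternity, rng)
    paths["markers"] = out / "markers.tsv"
    write_marker_tsv(panel, roles, paths["markers"])
    truth.true_fathers = fathers

    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# Truth derivation for organelle anomalies (pure layout arithmetic)


def _derive_organelle_truth(config: SimulationConfig, truth: TruthTable) -> None:
    events = [
        (i.organelle, i.chrom, i.target_start, i.target_start + i.length,
         i.source_start, i.source_start + i.length)
        for i in config.insertions
    ]
    w = config.window_size
    end_distance = 500_000

    # end-proximal: both organelles within 500 kb of a terminus
    for chrom, L in config.chrom_lengths.items():
        for end in ("left", "right"):
            zone = (0, end_distance) if end == "left" else (L - end_distance, L)
            orgs = {
                org for org, c, s, e, *_ in events
                if c == chrom and s < zone[1] and e > zone[0]
            }
            if {"cp", "mt"} <= orgs:
                truth.end_proximal.append({"chrom": chrom, "end": end})

    # co-localized windows (both organelles, away from both termini)
    for chrom, L in config.chrom_lengths.items():
        n_windows = -(-L // w)
        for wi in range(n_windows):
            ws, we = wi * w, min((wi + 1) * w, L)
            if ws < end_distance or we > L - end_distance:
                continue
            orgs = {
                org for org, c, s, e, *_ in events
                if c == chrom and s < we and e > ws
            }
            if {"cp", "mt"} <= orgs:
                truth.co_localized_windows.append({"chrom": chrom, "start": ws, "stop": we})

    # hotspot: windows with pooled event coverage >= 0.5 forming >= 1 Mb runs
    for chrom, L in config.chrom_lengths.items():
        n_windows = L // w
        dense = []
        for wi in range(n_windows):
            ws, we = wi * w, (wi + 1) * w
            cov = sum(
                max(0, min(e, we) - max(s, ws))
                for org, c, s, e, *_ in events
                if c == chrom
            )
            dense.append(cov / (we - ws) >= 0.5)
        i = 0
        while i < n_windows:
            if dense[i]:
                j = i
                while j + 1 < n_windows and dense[j + 1]:
                    j += 1
                if (j - i + 1) * w >= 1_000_000:
                    truth.hotspots.append({"chrom": chrom, "start": i * w, "stop": (j + 1) * w})
                i = j + 1
            else:
                i += 1

    # tandem-like: groups of >= 3 same-organelle events within 200 kb whose
    # source spans pairwise overlap >= 50% of the shorter span
    for org in ("cp", "mt"):
        ev = sorted(
            [e for e in events if e[0] == org], key=lambda e: (e[1], e[2])
        )
        clusters: List[List[tuple]] = []
        for e in ev:
            if clusters and clusters[-1][-1][1] == e[1] and e[2] - clusters[-1][-1][3] <= 200_000:
                clusters[-1].append(e)
            else:
                clusters.append([e])
        for cluster in clusters:
            if len(cluster) < 3:
                continue
            best: List[tuple] = []
            for seed_e in cluster:
                grp = [seed_e]
                for e in cluster:
                    if e is seed_e:
                        continue
                    if all(_recip(e[4], e[5], g[4], g[5]) >= 0.5 for g in grp):
                        grp.append(e)
                if len(grp) > len(best):
                    best = grp
            if len(best) >= 3:
                truth.tandem_like.append(
                    {"chrom": best[0][1], "organelle": org,
                     "start": min(e[2] for e in best), "stop": max(e[3] for e in best),
                     "n_events": len(best)}
                )


def _recip(a0: int, a1: int, b0: int, b1: int) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    if hi <= lo:
        return 0.0
    return (hi - lo) / min(a1 - a0, b1 - b0)


# ---------------------------------------------------------------------------
# SNP simulation


def _simulate_snps(
    config: SimulationConfig,
    genome: Genome,
    grid: WindowGrid,
    rng: np.random.Generator,
):
    plan = config.snp
    low_lookup: Dict[str, Tuple[int, int, float, float]] = {}
    for chrom, start, stop, het_d, hom_d in plan.low_het_regions:
        low_lookup[chrom] = (start, stop, het_d, hom_d)

    exclusion: Dict[str, List[Tuple[int, int]]] = {}
    for g in config.gaps:
        exclusion.setdefault(g.chrom, []).append((g.start - 3, g.start + g.length + 3))

    sites: List[PileupSite] = []
    consensus: Dict[Tuple[str, int], str] = {}
    rows: List[Tuple[str, int, str]] = []

    def draw_depth(n: int) -> np.ndarray:
        if plan.noiseless:
            return np.full(n, int(plan.depth_mean))
        return rng.poisson(plan.depth_mean, size=n)

    for chrom, tiles in grid.windows.items():
        seq = genome.sequences[chrom]
        zones = exclusion.get(chrom, [])
        taken: set = set()

        def ok(pos: int) -> bool:
            if pos in taken or seq[pos] == "N":
                return False
            return not any(lo <= pos < hi for lo, hi in zones)

        def draw_positions(w: GenomicInterval, n: int) -> List[int]:
            if n <= 0:
                return []
            cand = w.start + rng.choice(w.length, size=min(3 * n + 10, w.length), replace=False)
            chosen = []
            for p in cand:
                p = int(p)
                if ok(p):
                    chosen.append(p)
                    taken.add(p)
                    if len(chosen) == n:
                        break
            return chosen

        for w in tiles:
            het_d, hom_d = plan.het_per_window, plan.hom_per_window
            low = low_lookup.get(chrom)
            if low and low[0] <= w.start and w.end <= low[1]:
                het_d, hom_d = low[2], low[3]
            n_het = int(het_d) if plan.noiseless else int(rng.poisson(het_d))
            n_hom = int(hom_d) if plan.noiseless else int(rng.poisson(hom_d))
            het_pos = draw_positions(w, n_het)
            hom_pos = draw_positions(w, n_hom)
            depths = draw_depth(len(het_pos))
            for p, d in zip(het_pos, depths):
                d = max(int(d), 1)
                ref = seq[p]
                alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                n_alt = d // 2 if plan.noiseless else int(rng.binomial(d, 0.5))
                sites.append(PileupSite(chrom, p, ref, {ref: d - n_alt, alt: n_alt}))
                rows.append((chrom, p, "het"))
            for p in hom_pos:
                d = max(int(draw_depth(1)[0]), 1)
                ref = seq[p]
                other = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                sites.append(PileupSite(chrom, p, ref, {ref: d}))
                consensus[(chrom, p)] = other
                rows.append((chrom, p, "hom_diff"))

        # homozygous-alternate sites (assembly disagreement within A)
        L = genome.lengths[chrom]
        for _ in range(plan.hom_alt_sites_per_chrom):
            p = int(rng.integers(20_000, L - 20_000))
            while not ok(p):
                p = int(rng.integers(20_000, L - 20_000))
            taken.add(p)
            ref = seq[p]
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            d = max(int(draw_depth(1)[0]), 12)
            sites.append(PileupSite(chrom, p, ref, {ref: 0, alt: d}))
            rows.append((chrom, p, "hom_alt"))
        # low-depth sites
        for _ in range(plan.low_depth_sites_per_chrom):
            p = int(rng.integers(20_000, L - 20_000))
            while not ok(p):
                p = int(rng.integers(20_000, L - 20_000))
            taken.add(p)
            ref = seq[p]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            sites.append(PileupSite(chrom, p, ref, {ref: 3, alt: 2}))
            rows.append((chrom, p, "low_depth"))
        # near-gap sites: classified no_call regardless of counts
        for g in config.gaps:
            if g.chrom != chrom:
                continue
            p = g.start - 2
            if p >= 0 and seq[p] != "N" and p not in taken:
                taken.add(p)
                ref = seq[p]
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                sites.append(PileupSite(chrom, p, ref, {ref: 15, alt: 15}))
                rows.append((chrom, p, "near_gap"))

    sites.sort(key=lambda s: (s.chrom, s.pos))
    site_truth = pd.DataFrame(rows, columns=["chrom", "pos", "true_state"]).sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    return sites, consensus, site_truth


# ---------------------------------------------------------------------------
# Mapping population


def _simulate_mapping(plan: MappingPlan, rng: np.random.Generator):
    n = plan.n_offspring
    individuals = [f"hs{i + 1:03d}" for i in range(n)]
    locus_ids, contigs, positions = [], [], []
    classes: Dict[str, str] = {}
    planted: List[str] = []
    geno_rows, depth_rows = [], []
    for ci in range(plan.n_contigs):
        contig = f"ctg{ci + 1:02d}"
        for li, (cls, n_het) in enumerate(plan.class_het_counts):
            locus = f"{contig}_l{li + 1}"
            locus_ids.append(locus)
            contigs.append(contig)
            positions.append(100 + 200 * li)
            classes[locus] = cls
            if cls == "1:1":
                planted.append(locus)
            order = rng.permutation(n)
            geno = np.where(np.isin(np.arange(n), order[:n_het]), "het", "hom").astype(object)
            if plan.error_rate > 0:
                flip = rng.random(n) < plan.error_rate
                geno[flip] = np.where(geno[flip] == "het", "hom", "het")
            if plan.missing_rate > 0:
                geno[rng.random(n) < plan.missing_rate] = None
            depth = plan.depth_floor + rng.poisson(plan.depth_extra_mean, size=n)
            geno_rows.append(geno)
            depth_rows.append(depth)
    geno_df = pd.DataFrame(geno_rows, index=locus_ids, columns=individuals, dtype=object)
    depth_df = pd.DataFrame(np.array(depth_rows), index=locus_ids, columns=individuals)
    loci = pd.DataFrame({"contig": contigs, "position": positions}, index=locus_ids)
    return GenotypeMatrix(geno_df, depth_df, loci), classes, planted


# ---------------------------------------------------------------------------
# Paternity panel


def simulate_paternity_panel(plan: PaternityPlan, seed: int):
    """Standalone paternity panel: (individuals, roles, true fathers)."""
    return _simulate_paternity(plan, np.random.default_rng(seed))


def simulate_genotype_matrix(plan: MappingPlan, seed: int):
    """Standalone mapping-population matrix: (matrix, classes, planted 1:1 loci)."""
    return _simulate_mapping(plan, np.random.default_rng(seed))


def _simulate_paternity(plan: PaternityPlan, rng: np.random.Generator):
    """Mother, candidate fathers and offspring over a marker panel.

    The panel emulates assay markers pre-screened for exclusion power:
    at loci where the mother is homozygous every candidate is
    homozygous, and the candidate allele codes are redrawn until every
    pair differs at ``min_pairwise_separation`` of these loci, which
    guarantees unique exclusion-based assignment at zero error.
    """
    loci = [f"l{i + 1:02d}" for i in range(plan.n_loci)]
    alleles = {}
    for locus in loci:
        i = int(rng.integers(0, 4))
        j = (i + 1 + int(rng.integers(0, 3))) % 4
        alleles[locus] = ("ACGT"[i], "ACGT"[j])
    het_loci = set(rng.choice(plan.n_loci, size=plan.n_mother_het, replace=False).tolist())
    mother_geno: Dict[str, Tuple[str, str]] = {}
    for k, locus in enumerate(loci):
        a, b = alleles[locus]
        mother_geno[locus] = tuple(sorted((a, b))) if k in het_loci else (a, a) if rng.random() < 0.5 else (b, b)

    names = ["MOTHER"] + [f"F{i + 1:02d}" for i in range(plan.n_candidates)]
    hom_loci = [locus for k, locus in enumerate(loci) if k not in het_loci]

    def draw_codes() -> Dict[str, Dict[str, str]]:
        codes: Dict[str, Dict[str, str]] = {}
        for name in names:
            if name == "MOTHER":
                codes[name] = {locus: mother_geno[locus][0] for locus in hom_loci}
            else:
                codes[name] = {
                    locus: alleles[locus][int(rng.integers(0, 2))] for locus in hom_loci
                }
        return codes

    codes = draw_codes()
    for _ in range(100):
        min_sep = min(
            sum(codes[a][locus] != codes[b][locus] for locus in hom_loci)
            for ai, a in enumerate(names)
            for b in names[ai + 1:]
        )
        if min_sep >= plan.min_pairwise_separation:
            break
        codes = draw_codes()
    else:
        raise RuntimeError("could not draw a separable candidate panel")

    candidates: List[MarkerGenotypes] = []
    for name in names:
        geno: Dict[str, Tuple[str, str]] = {}
        for k, locus in enumerate(loci):
            if name == "MOTHER":
                geno[locus] = mother_geno[locus]
            elif k in het_loci:
                a, b = alleles[locus]
                u = rng.random()
                geno[locus] = (a, a) if u < 0.25 else (b, b) if u < 0.5 else tuple(sorted((a, b)))
            else:
                geno[locus] = (codes[name][locus], codes[name][locus])
        candidates.append(MarkerGenotypes(individual=name, genotypes=geno))

    by_name = {c.individual: c for c in candidates}
    offspring: List[MarkerGenotypes] = []
    fathers: Dict[str, str] = {}
    for oi in range(plan.n_offspring):
        name = f"o{oi + 1:03d}"
        father = names[oi % len(names)]
        fathers[name] = father
        geno: Dict[str, Optional[Tuple[str, str]]] = {}
        for locus in loci:
            if rng.random() < plan.missing_rate:
                geno[locus] = None
                continue
            mat = mother_geno[locus][int(rng.integers(0, 2))]
            pat = by_name[father].genotypes[locus][int(rng.integers(0, 2))]
            pair = tuple(sorted((mat, pat)))
            if plan.error_rate > 0 and rng.random() < plan.error_rate:
                a, b = alleles[locus]
                u = rng.random()
                pair = (a, a) if u < 1 / 3 else (b, b) if u < 2 / 3 else tuple(sorted((a, b)))
            geno[locus] = pair
        offspring.append(MarkerGenotypes(individual=name, genotypes=geno))

    roles = {name: ("mother" if name == "MOTHER" else "candidate") for name in names}
    roles.update({o.individual: "offspring" for o in offspring})
    return candidates + offspring, roles, fathers
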
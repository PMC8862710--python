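"""SNP classification by allele balance and windowed density anomalies.

Within-individual (heterozygous) SNPs are called from per-site pileup
counts: a site with sequencing depth >= 10 that is not within 3 bp of an
assembly gap is heterozygous when the alternate-allele fraction lies in
[0.25, 0.75), homozygous-alternate when it is >= 0.75 and reference
below 0.25.  Between-individual (homozygous) SNPs are sites where the
first individual is homozygous and the second individual's consensus
base differs.  Both classes are profiled in non-overlapping 100 kb
windows, split into genic and intergenic counts, and screened for the
landscape anomalies of interest: multi-Mb stretches almost free of
heterozygous SNPs, windows where genic and intergenic densities are
uncoupled, and repeat-rich / duplicated-gene regions.

A note on the allele-balance ratio: the rule is implemented on the
alternate-allele *fraction* ``alt / (ref + alt)``.  A literal
alternate-to-reference ratio would classify a perfectly balanced 50/50
site as homozygous (ratio 1.0 >= 0.75), defeating the purpose of the
test; the literal reading remains selectable via ``ratio_mode``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    Genome,
    GenomicInterval,
    PileupSite,
    WindowGrid,
    merge_intervals,
)

STATES = ("heterozygous", "homozygous_alt", "reference", "no_call")


@dataclass
class SnpCall:
    """Classification of one pileup site."""

    chrom: str
    pos: int
    ref_base: str
    state: str
    alt_fraction: float
    reason: str = "ok"  # ok | low_depth | near_gap | monoallelic
    alt_base: Optional[str] = None
    depth: int = 0

    @property
    def consensus_base(self) -> str:
        """The individual's consensus base at this site."""
        if self.state == "homozygous_alt" and self.alt_base:
            return self.alt_base
        return self.ref_base


@dataclass
class InterIndividualSnp:
    """A homozygous difference between the two individuals."""

    chrom: str
    pos: int
    kind: str  # always "homozygous_diff"
    basis: str  # the second individual's consensus base


@dataclass
class SnpWindowProfile:
    """Per-window het/hom counts with genic/intergenic splits.

    ``table`` columns: chrom, start, end, het_count, hom_count,
    genic_het, genic_hom, intergenic_het, intergenic_hom,
    gene_fraction.  Genic + intergenic = total in every window.
    """

    grid: WindowGrid
    table: pd.DataFrame


@dataclass
class AnomalyRegionSnp:
    type: str  # low_het | low_both | decoupled_genic | repeat_rich | dup_gene_cluster
    interval: GenomicInterval
    stats: Dict[str, float] = field(default_factory=dict)
    extended: bool = False


# ---------------------------------------------------------------------------
# Site classification


class _GapIndex:
    """Sorted exclusion zones (gap +/- flank) per chromosome."""

    def __init__(self, gaps: Iterable[GenomicInterval], flank: int):
        zones = [
            GenomicInterval(g.chrom, max(0, g.start - flank), g.end + flank) for g in gaps
        ]
        self.by_chrom: Dict[str, Tuple[List[int], List[int]]] = {}
        for iv in merge_intervals(zones):
            starts, ends = self.by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def near_gap(self, chrom: str, pos: int) -> bool:
        if chrom not in self.by_chrom:
            return False
        starts, ends = self.by_chrom[chrom]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]


def classify_site(
    site: PileupSite,
    gaps: Iterable[GenomicInterval] = (),
    min_depth: int = 10,
    gap_flank: int = 3,
    ratio_mode: str = "alt_fraction",
    _gap_index: Optional[_GapIndex] = None,
) -> SnpCall:
    """Classify one pileup site as het / hom-alt / reference / no-call.

    Gates first: depth below ``min_depth`` (including depth 0) is a
    no-call with reason ``low_depth``; positions within ``gap_flank``
    bases of an assembly gap are no-calls with reason ``near_gap``.
    Otherwise the alternate fraction (all non-reference bases pooled,
    ``(depth - ref) / depth``) is thresholded half-open: < 0.25 is
    reference, [0.25, 0.75) heterozygous, >= 0.75 homozygous-alternate.
    """
    gap_index = _gap_index if _gap_index is not None else _GapIndex(gaps, gap_flank)
    depth = site.depth
    alt_base = _major_alt(site)
    if depth < min_depth:
        return SnpCall(site.chrom, site.pos, site.ref_base, "no_call", 0.0, "low_depth", alt_base, depth)
    if gap_index.near_gap(site.chrom, site.pos):
        return SnpCall(site.chrom, site.pos, site.ref_base, "no_call", 0.0, "near_gap", alt_base, depth)
    ref = site.counts.get(site.ref_base, 0)
    alt = depth - ref
    if ratio_mode == "alt_fraction":
        ratio = alt / depth
    elif ratio_mode == "alt_ref":
        if ref == 0:
            ratio = float("inf")
        else:
            ratio = alt / ref
    else:
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    if ratio >= 0.75:
        state = "homozygous_alt"
    elif ratio >= 0.25:
        state = "heterozygous"
    else:
        state = "reference"
    frac = alt / depth
    return SnpCall(site.chrom, site.pos, site.ref_base, state, frac, "ok", alt_base, depth)


def _major_alt(site: PileupSite) -> Optional[str]:
    alts = {b: n for b, n in site.counts.items() if b != site.ref_base and n > 0}
    if not alts:
        return None
    return max(sorted(alts), key=lambda b: alts[b])


def classify_pileup(
    sites: Iterable[PileupSite],
    gaps: Iterable[GenomicInterval] = (),
    min_depth: int = 10,
    gap_flank: int = 3,
    ratio_mode: str = "alt_fraction",
) -> List[SnpCall]:
    """Classify many sites sharing one gap index (bulk entry point)."""
    gap_index = _GapIndex(gaps, gap_flank)
    return [
        classify_site(s, min_depth=min_depth, gap_flank=gap_flank,
                      ratio_mode=ratio_mode, _gap_index=gap_index)
        for s in sites
    ]


def call_inter_individual(
    calls_a: Iterable[SnpCall],
    consensus_b: Dict[Tuple[str, int], str],
) -> List[InterIndividualSnp]:
    """Homozygous differences: A homozygous, B's consensus base differs.

    Sites where A is heterozygous or a no-call are never emitted; B
    consensus bases outside ACGT are skipped with a logged count.
    """
    import logging

    out: List[InterIndividualSnp] = []
    skipped = 0
    for call in calls_a:
        if call.state not in ("reference", "homozygous_alt"):
            continue
        base_b = consensus_b.get((call.chrom, call.pos))
        if base_b is None:
            continue
        if base_b not in "ACGT":
            skipped += 1
            continue
        if base_b != call.consensus_base:
            out.append(InterIndividualSnp(call.chrom, call.pos, "homozygous_diff", base_b))
    if skipped:
        logging.getLogger(__name__).info(
            "call_inter_individual: skipped %d sites with non-ACGT consensus", skipped
        )
    return out


# ---------------------------------------------------------------------------
# Window profiling


class _GenicIndex:
    """Merged gene (or CDS/exon) intervals for odd/even stabbing queries."""

    def __init__(self, genes: Iterable[GeneModel], mode: str = "gene"):
        if mode == "gene":
            ivs = [g.interval for g in genes]
        elif mode == "cds":
            ivs = [e for g in genes for e in g.exons]
        else:
            raise ValueError(f"unknown genic mode {mode!r}")
        self.merged = merge_intervals(ivs)
        self.by_chrom: Dict[str, np.ndarray] = {}
        for chrom in {iv.chrom for iv in self.merged}:
            bounds: List[int] = []
            for iv in self.merged:
                if iv.chrom == chrom:
                    bounds += [iv.start, iv.end]
            self.by_chrom[chrom] = np.array(bounds)

    def genic(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: position lies within a gene span (half-open)."""
        if chrom not in self.by_chrom:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(self.by_chrom[chrom], pos, side="right")
        return idx % 2 == 1


def profile_snp_windows(
    calls: Iterable[SnpCall],
    inter: Iterable[InterIndividualSnp],
    genes: Iterable[GeneModel],
    grid: WindowGrid,
    genic_mode: str = "gene",
) -> SnpWindowProfile:
    """Count het and hom SNPs per window, split genic/intergenic.

    A SNP is genic iff its position falls inside any gene interval
    (introns included); ``genic_mode='cds'`` restricts to exons.
    """
    genic_index = _GenicIndex(genes, genic_mode)
    rows = []
    het_pos: Dict[str, List[int]] = {}
    hom_pos: Dict[str, List[int]] = {}
    for c in calls:
        if c.state == "heterozygous":
            het_pos.setdefault(c.chrom, []).append(c.pos)
    for s in inter:
        hom_pos.setdefault(s.chrom, []).append(s.pos)

    for chrom, tiles in grid.windows.items():
        n = len(tiles)
        het = np.array(sorted(het_pos.get(chrom, [])), dtype=np.int64)
        hom = np.array(sorted(hom_pos.get(chrom, [])), dtype=np.int64)
        het_w = np.bincount(het // grid.window_size, minlength=n) if len(het) else np.zeros(n, int)
        hom_w = np.bincount(hom // grid.window_size, minlength=n) if len(hom) else np.zeros(n, int)
        het_genic_mask = genic_index.genic(chrom, het) if len(het) else np.zeros(0, bool)
        hom_genic_mask = genic_index.genic(chrom, hom) if len(hom) else np.zeros(0, bool)
        het_g = (
            np.bincount(het[het_genic_mask] // grid.window_size, minlength=n)
            if het_genic_mask.any()
            else np.zeros(n, int)
        )
        hom_g = (
            np.bincount(hom[hom_genic_mask] // grid.window_size, minlength=n)
            if hom_genic_mask.any()
            else np.zeros(n, int)
        )
        gene_cov = _gene_coverage(genic_index, grid, chrom)
        for i, w in enumerate(tiles):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w.start,
                    "end": w.end,
                    "het_count": int(het_w[i]),
                    "hom_count": int(hom_w[i]),
                    "genic_het": int(het_g[i]),
                    "genic_hom": int(hom_g[i]),
                    "intergenic_het": int(het_w[i] - het_g[i]),
                    "intergenic_hom": int(hom_w[i] - hom_g[i]),
                    "gene_fraction": float(gene_cov[i] / w.length),
                }
            )
    return SnpWindowProfile(grid=grid, table=pd.DataFrame(rows))


def _gene_coverage(genic_index: _GenicIndex, grid: WindowGrid, chrom: str) -> np.ndarray:
    from .core import coverage_per_window

    ivs = [iv for iv in genic_index.merged if iv.chrom == chrom]
    if not ivs:
        return np.zeros(len(grid.windows[chrom]), dtype=np.int64)
    return coverage_per_window(ivs, grid, chrom)


# ---------------------------------------------------------------------------
# Landscape anomaly screens


def detect_low_het_regions(
    profile: SnpWindowProfile,
    min_span: int = 1_000_000,
    het_quantile: float = 0.1,
    flag_span: int = 5_000_000,
) -> List[AnomalyRegionSnp]:
    """Maximal runs of windows with het counts in the genome-wide low tail.

    Windows whose het count is at or below the genome-wide
    ``het_quantile`` quantile *and* strictly below the genome median are
    "low" (the median guard means a flat profile has no anomalously low
    windows); maximal runs of low windows spanning at least ``min_span``
    are reported, marked ``extended`` from ``flag_span`` up.  A run
    whose mean hom count is also in the low hom tail is typed
    ``low_both`` (the repeat-anomaly signature); otherwise ``low_het``.
    """
    table = profile.table
    if len(table) < 10:
        raise ValueError(f"insufficient windows for quantile thresholds ({len(table)} < 10)")
    het_thr = float(np.quantile(table["het_count"], het_quantile))
    hom_thr = float(np.quantile(table["hom_count"], het_quantile))
    het_median = float(table["het_count"].median())
    hom_median = float(table["hom_count"].median())
    out: List[AnomalyRegionSnp] = []
    genome_het_mean = float(table["het_count"].mean())
    genome_hom_mean = float(table["hom_count"].mean())
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        low = ((sub["het_count"] <= het_thr) & (sub["het_count"] < het_median)).to_numpy()
        i = 0
        while i < len(sub):
            if not low[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and low[j + 1]:
                j += 1
            start, end = int(sub.loc[i, "start"]), int(sub.loc[j, "end"])
            if end - start >= min_span:
                run = sub.loc[i:j]
                run_hom = float(run["hom_count"].mean())
                low_both = run_hom <= hom_thr and run_hom < hom_median
                out.append(
                    AnomalyRegionSnp(
                        type="low_both" if low_both else "low_het",
                        interval=GenomicInterval(chrom, start, end),
                        stats={
                            "mean_het_in": float(run["het_count"].mean()),
                            "mean_hom_in": float(run["hom_count"].mean()),
                            "mean_het_genome": genome_het_mean,
                            "mean_hom_genome": genome_hom_mean,
                            "het_threshold": het_thr,
                        },
                        extended=end - start >= flag_span,
                    )
                )
            i = j + 1
    return out


def detect_decoupled_windows(profile: SnpWindowProfile) -> List[AnomalyRegionSnp]:
    """Windows where genic and intergenic SNP densities are uncoupled.

    Reported when the overall het count is strictly in the top quartile
    while the genic het count is strictly in the bottom quartile despite
    a gene fraction at or above the genome median (conserved-gene
    signature), or the homozygous mirror case: overall hom strictly
    bottom-quartile with genic hom strictly top-quartile (diversifying
    genes).  Windows with no genes never qualify.  Quartiles are
    genome-wide; this is a screening rank statistic, so a handful of
    flagged windows is expected even on homogeneous genomes.
    """
    t = profile.table
    med_gene = float(t["gene_fraction"].median())
    het_q3 = float(np.quantile(t["het_count"], 0.75))
    ghet_q1 = float(np.quantile(t["genic_het"], 0.25))
    hom_q1 = float(np.quantile(t["hom_count"], 0.25))
    ghom_q3 = float(np.quantile(t["genic_hom"], 0.75))
    out: List[AnomalyRegionSnp] = []
    for _, row in t.iterrows():
        if row["gene_fraction"] < med_gene or row["gene_fraction"] == 0:
            continue
        conserved = row["het_count"] > het_q3 and row["genic_het"] < ghet_q1
        diversifying = row["hom_count"] < hom_q1 and row["genic_hom"] > ghom_q3
        if conserved or diversifying:
            out.append(
                AnomalyRegionSnp(
                    type="decoupled_genic",
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    stats={
                        "het_count": float(row["het_count"]),
                        "genic_het": float(row["genic_het"]),
                        "hom_count": float(row["hom_count"]),
                        "genic_hom": float(row["genic_hom"]),
                        "gene_fraction": float(row["gene_fraction"]),
                        "kind": "conserved" if conserved else "diversifying",
                    },
                )
            )
    return out


def window_count_histogram(
    profile: SnpWindowProfile, bins: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Histogram of per-window SNP counts, separately for het and hom.

    Returns a table with ``bin_left``, ``bin_right``, ``het_windows``,
    ``hom_windows``; both columns sum to the total window count.
    """
    t = profile.table
    if len(t) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "het_windows", "hom_windows"])
    if bins is None:
        top = max(int(t["het_count"].max()), int(t["hom_count"].max()), 1)
        step = max(1, top // 20)
        bins = list(range(0, top + 2 * step, step))
    het_hist, edges = np.histogram(t["het_count"], bins=bins)
    hom_hist, _ = np.histogram(t["hom_count"], bins=bins)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "het_windows": het_hist,
            "hom_windows": hom_hist,
        }
    )


def detect_repeat_gene_anomalies(
    repeat_fraction: pd.DataFrame,
    genes: Iterable[GeneModel],
    grid: WindowGrid,
    repeat_threshold: float = 0.7,
    window_fraction: float = 0.9,
    min_span: int = 5_000_000,
    dup_fraction: float = 0.2,
    dup_min_span: int = 1_000_000,
) -> List[AnomalyRegionSnp]:
    """Repeat-rich regions and duplicated-gene clusters.

    (a) Maximal regions of at least ``min_span`` in which at least
    ``window_fraction`` of windows have repeat-covered fraction above
    ``repeat_threshold``: runs of above-threshold windows are found
    first, then adjacent runs are merged while the pooled above-fraction
    stays at or above ``window_fraction``.

    (b) Regions of at least ``dup_min_span`` where the fraction of
    duplication-flagged genes exceeds ``dup_fraction``, from a sliding
    ``dup_min_span`` window advanced one grid window at a time, with
    qualifying placements merged.

    ``repeat_fraction`` needs columns chrom/start/end/repeat_fraction.
    """
    genes = list(genes)
    out: List[AnomalyRegionSnp] = []

    for chrom, sub in repeat_fraction.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        above = (sub["repeat_fraction"] > repeat_threshold).to_numpy()
        runs: List[Tuple[int, int]] = []  # inclusive window index ranges
        i = 0
        while i < len(sub):
            if above[i]:
                j = i
                while j + 1 < len(sub) and above[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        # merge adjacent runs while the pooled above-window fraction holds
        merged_runs: List[Tuple[int, int]] = []
        for run in runs:
            if merged_runs:
                lo, _ = merged_runs[-1]
                hi = run[1]
                frac = above[lo : hi + 1].mean()
                if frac >= window_fraction:
                    merged_runs[-1] = (lo, hi)
                    continue
            merged_runs.append(run)
        for lo, hi in merged_runs:
            start, end = int(sub.loc[lo, "start"]), int(sub.loc[hi, "end"])
            if end - start >= min_span:
                out.append(
                    AnomalyRegionSnp(
                        type="repeat_rich",
                        interval=GenomicInterval(chrom, start, end),
                        stats={
                            "windows": float(hi - lo + 1),
                            "fraction_above": float(above[lo : hi + 1].mean()),
                            "mean_repeat_fraction": float(
                                sub.loc[lo:hi, "repeat_fraction"].mean()
                            ),
                        },
                    )
                )

    # (b) duplicated-gene clusters
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, tiles in grid.windows.items():
        chrom_genes = sorted(by_chrom.get(chrom, []), key=lambda g: g.interval.start)
        if not chrom_genes:
            continue
        starts = np.array([g.interval.start for g in chrom_genes])
        flags = np.array([g.duplication_flag for g in chrom_genes])
        length = tiles[-1].end
        qualifying: List[Tuple[int, int]] = []
        for w in tiles:
            lo, hi = w.start, min(w.start + dup_min_span, length)
            if hi - lo < dup_min_span:
                break
            sel = (starts >= lo) & (starts < hi)
            n = int(sel.sum())
            if n and flags[sel].mean() > dup_fraction:
                qualifying.append((lo, hi))
        for lo, hi in qualifying:
            if out and out[-1].type == "dup_gene_cluster" and out[-1].interval.chrom == chrom and lo <= out[-1].interval.end:
                prev = out[-1].interval
                out[-1].interval = GenomicInterval(chrom, prev.start, max(prev.end, hi))
            else:
                sel = (starts >= lo) & (starts < hi)
                out.append(
                    AnomalyRegionSnp(
                        type="dup_gene_cluster",
                        interval=GenomicInterval(chrom, lo, hi),
                        stats={"dup_fraction": float(flags[sel].mean()), "n_genes": float(sel.sum())},
                    )
                )
    return out


def repeat_fraction_profile(
    repeat_intervals: List[GenomicInterval], grid: WindowGrid
) -> pd.DataFrame:
    """Per-window repeat-covered fraction from repeat annotation intervals."""
    from .core import coverage_per_window

    rows = []
    for chrom, tiles in grid.windows.items():
        cov = coverage_per_window(repeat_intervals, grid, chrom)
        for i, w in enumerate(tiles):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w.start,
                    "end": w.end,
                    "repeat_fraction": float(cov[i] / w.length),
                }
            )
    return pd.DataFrame(rows)
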
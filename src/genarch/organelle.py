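"""Nuclear insertions of organelle DNA (NUPT/NUMT) and their anomalies.

Alignment hits of the separately assembled chloroplast (cp) and
mitochondrial (mt) genomes against the nuclear assembly are filtered
(identity >= 95%, length >= 100 bp, e-value <= 1e-10), merged into
insertion events where their nuclear target spans overlap or abut, and
tabulated per 100 kb window at nested length tiers (>=100 bp, >=1 kb,
>=5 kb, >=10 kb).  Four anomaly patterns are screened for: insertion
hotspots (multi-Mb stretches mostly covered by events of both
organelles), tandem-like integrations (clustered events re-using the
same organelle source span), end-proximal integrations of both
organelles, and cp/mt co-localization within single windows away from
the chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AlignmentHit,
    Genome,
    GenomicInterval,
    WindowGrid,
    coverage_per_window,
    merge_intervals,
)

TIER_THRESHOLDS = (100, 1_000, 5_000, 10_000)


@dataclass
class InsertionEvent:
    """A merged organelle-to-nucleus insertion locus."""

    organelle: str  # "cp" | "mt"
    target: GenomicInterval
    source_spans: List[Tuple[int, int]]
    max_identity: float
    tiers: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.tiers:
            self.tiers = tiers_for_length(self.length)

    @property
    def length(self) -> int:
        return self.target.length


def tiers_for_length(length: int, thresholds: Sequence[int] = TIER_THRESHOLDS) -> Tuple[int, ...]:
    """Exactly those tier thresholds that the event length reaches."""
    return tuple(t for t in thresholds if length >= t)


@dataclass
class InsertionWindowProfile:
    """Per-window, per-organelle, per-tier event counts.

    ``counts`` has one row per window (chrom, start, end) and one column
    per ``(organelle, tier)`` pair named ``{organelle}_ge{tier}``.  An
    event contributes to every window its target overlaps.
    """

    grid: WindowGrid
    counts: pd.DataFrame


@dataclass
class AnomalyRegionOrg:
    """An organelle-integration anomaly region with its evidence."""

    type: str  # hotspot | tandem_like | end_proximal | co_localized
    interval: GenomicInterval
    evidence: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 95.0,
    min_length: int = 100,
    max_evalue: float = 1e-10,
) -> List[AlignmentHit]:
    """Keep hits meeting the identity, length and e-value floors."""
    return [
        h
        for h in hits
        if h.identity >= min_identity and h.aln_length >= min_length and h.evalue <= max_evalue
    ]


def merge_hits_to_events(
    hits: Iterable[AlignmentHit],
    organelle: Optional[str] = None,
    max_gap: int = 0,
) -> List[InsertionEvent]:
    """Merge hits of one organelle into insertion events.

    Hits whose nuclear target intervals overlap or abut within
    ``max_gap`` become one event; source spans are concatenated,
    ``max_identity`` is the maximum over members and length tiers are
    assigned from the merged target length.
    """
    hits = sorted(hits, key=lambda h: (h.target.chrom, h.target.start, h.target.end))
    if not hits:
        return []
    if organelle is None:
        organelle = hits[0].source_id
    events: List[InsertionEvent] = []
    cur: List[AlignmentHit] = [hits[0]]
    cur_end = hits[0].target.end
    for h in hits[1:]:
        if h.target.chrom == cur[0].target.chrom and h.target.start <= cur_end + max_gap:
            cur.append(h)
            cur_end = max(cur_end, h.target.end)
        else:
            events.append(_build_event(cur, organelle))
            cur, cur_end = [h], h.target.end
    events.append(_build_event(cur, organelle))
    return events


def _build_event(members: List[AlignmentHit], organelle: str) -> InsertionEvent:
    target = GenomicInterval(
        members[0].target.chrom,
        min(h.target.start for h in members),
        max(h.target.end for h in members),
    )
    return InsertionEvent(
        organelle=organelle,
        target=target,
        source_spans=[(h.source_start, h.source_end) for h in members],
        max_identity=max(h.identity for h in members),
    )


def count_events_per_window(
    events: Iterable[InsertionEvent],
    grid: WindowGrid,
    tiers: Sequence[int] = (100, 1_000, 10_000),
) -> InsertionWindowProfile:
    """Count events overlapping each window, per organelle and tier.

    A tier column counts events *at least* that long, so counts are
    monotonically non-increasing across increasing tiers.
    """
    events = list(events)
    organelles = sorted({e.organelle for e in events}) or ["cp", "mt"]
    rows = [
        {"chrom": chrom, "start": w.start, "end": w.end}
        for chrom, _, w in grid.iter_windows()
    ]
    counts = pd.DataFrame(rows)
    offsets = {}
    pos = 0
    for chrom, tiles in grid.windows.items():
        offsets[chrom] = pos
        pos += len(tiles)
    for org in organelles:
        for t in tiers:
            counts[f"{org}_ge{t}"] = 0
    for e in events:
        if e.target.chrom not in grid.windows:
            raise KeyError(f"event on unknown chromosome {e.target.chrom!r}")
        for wi in grid.window_range(e.target):
            row = offsets[e.target.chrom] + wi
            for t in tiers:
                if e.length >= t:
                    counts.loc[row, f"{e.organelle}_ge{t}"] += 1
    return InsertionWindowProfile(grid=grid, counts=counts)


# ---------------------------------------------------------------------------
# Anomaly screens


def detect_end_proximal(
    events: Iterable[InsertionEvent],
    genome_or_lengths,
    end_distance: int = 500_000,
) -> List[AnomalyRegionOrg]:
    """Chromosome ends with insertions of *both* organelles nearby.

    An end is flagged when at least one cp and one mt event overlap the
    terminal ``end_distance`` of the chromosome.
    """
    lengths = (
        genome_or_lengths.lengths if isinstance(genome_or_lengths, Genome) else genome_or_lengths
    )
    events = list(events)
    out: List[AnomalyRegionOrg] = []
    for chrom, length in lengths.items():
        zones = {
            "left": GenomicInterval(chrom, 0, min(end_distance, length)),
            "right": GenomicInterval(chrom, max(0, length - end_distance), length),
        }
        for end, zone in zones.items():
            near = [e for e in events if e.target.overlaps(zone)]
            n_cp = sum(1 for e in near if e.organelle == "cp")
            n_mt = sum(1 for e in near if e.organelle == "mt")
            if n_cp >= 1 and n_mt >= 1:
                out.append(
                    AnomalyRegionOrg(
                        type="end_proximal",
                        interval=zone,
                        evidence={"end": end, "cp_events": n_cp, "mt_events": n_mt},
                    )
                )
    return out


def detect_co_localization(
    cp_events: Iterable[InsertionEvent],
    mt_events: Iterable[InsertionEvent],
    grid: WindowGrid,
    exclude_end_distance: int = 500_000,
) -> List[AnomalyRegionOrg]:
    """Windows away from both termini holding >=1 cp and >=1 mt event."""
    lengths = grid.lengths
    out: List[AnomalyRegionOrg] = []
    for chrom, tiles in grid.windows.items():
        length = lengths[chrom]
        cp_in = np.zeros(len(tiles), dtype=int)
        mt_in = np.zeros(len(tiles), dtype=int)
        for ev_set, acc in ((cp_events, cp_in), (mt_events, mt_in)):
            for e in ev_set:
                if e.target.chrom != chrom:
                    continue
                for wi in grid.window_range(e.target):
                    acc[wi] += 1
        for wi, w in enumerate(tiles):
            if w.start < exclude_end_distance or w.end > length - exclude_end_distance:
                continue
            if cp_in[wi] >= 1 and mt_in[wi] >= 1:
                out.append(
                    AnomalyRegionOrg(
                        type="co_localized",
                        interval=w,
                        evidence={"cp_events": int(cp_in[wi]), "mt_events": int(mt_in[wi])},
                    )
                )
    return out


def detect_hotspot(
    events: Iterable[InsertionEvent],
    grid: WindowGrid,
    min_span: int = 1_000_000,
    min_coverage_fraction: float = 0.5,
) -> List[AnomalyRegionOrg]:
    """Multi-window stretches mostly covered by pooled cp+mt events.

    Maximal runs of consecutive windows whose event-covered base
    fraction is at least ``min_coverage_fraction`` are reported when the
    run spans at least ``min_span``; evidence carries the covered bp per
    organelle inside the run.
    """
    events = list(events)
    out: List[AnomalyRegionOrg] = []
    for chrom, tiles in grid.windows.items():
        targets = [e.target for e in events if e.target.chrom == chrom]
        if not targets:
            continue
        covered = coverage_per_window(targets, grid, chrom)
        sizes = np.array([w.length for w in tiles])
        dense = covered / sizes >= min_coverage_fraction
        i = 0
        while i < len(tiles):
            if not dense[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(tiles) and dense[j + 1]:
                j += 1
            span = GenomicInterval(chrom, tiles[i].start, tiles[j].end)
            if span.length >= min_span:
                ev: Dict[str, float] = {"covered_fraction": float(covered[i : j + 1].sum() / sizes[i : j + 1].sum())}
                for org in ("cp", "mt"):
                    org_iv = [
                        e.target
                        for e in events
                        if e.organelle == org and e.target.chrom == chrom and e.target.overlaps(span)
                    ]
                    ev[f"{org}_covered_bp"] = float(
                        sum(iv.overlap_bp(span) for iv in merge_intervals(org_iv))
                    )
                    ev[f"{org}_events"] = float(len(org_iv))
                out.append(AnomalyRegionOrg(type="hotspot", interval=span, evidence=ev))
            i = j + 1
    return out


def _reciprocal_source_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """Overlap of two organelle source spans as a fraction of the shorter."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if hi <= lo:
        return 0.0
    shorter = min(a[1] - a[0], b[1] - b[0])
    return (hi - lo) / shorter


def _source_hull(e: InsertionEvent) -> Tuple[int, int]:
    return (min(s for s, _ in e.source_spans), max(t for _, t in e.source_spans))


def detect_tandem_like(
    events: Iterable[InsertionEvent],
    neighborhood: int = 200_000,
    min_events: int = 3,
    min_source_overlap: float = 0.5,
) -> List[AnomalyRegionOrg]:
    """Clusters of insertions re-using the same organelle source span.

    Events of one organelle within ``neighborhood`` of each other on the
    nucleus form candidate clusters; a cluster is tandem-like when at
    least ``min_events`` of its members have pairwise reciprocal source
    overlap of at least ``min_source_overlap`` (fraction of the shorter
    span).
    """
    events = sorted(events, key=lambda e: (e.target.chrom, e.target.start))
    clusters: List[List[InsertionEvent]] = []
    for e in events:
        if (
            clusters
            and clusters[-1][-1].target.chrom == e.target.chrom
            and e.target.start - clusters[-1][-1].target.end <= neighborhood
        ):
            clusters[-1].append(e)
        else:
            clusters.append([e])
    out: List[AnomalyRegionOrg] = []
    for cluster in clusters:
        if len(cluster) < min_events:
            continue
        best: List[InsertionEvent] = []
        for seed in cluster:
            group = [
                e
                for e in cluster
                if _reciprocal_source_overlap(_source_hull(seed), _source_hull(e))
                >= min_source_overlap
            ]
            # require *pairwise* overlap within the group
            ok = [seed]
            for e in group:
                if e is seed:
                    continue
                if all(
                    _reciprocal_source_overlap(_source_hull(e), _source_hull(g))
                    >= min_source_overlap
                    for g in ok
                ):
                    ok.append(e)
            if len(ok) > len(best):
                best = ok
        if len(best) >= min_events:
            iv = GenomicInterval(
                best[0].target.chrom,
                min(e.target.start for e in best),
                max(e.target.end for e in best),
            )
            out.append(
                AnomalyRegionOrg(
                    type="tandem_like",
                    interval=iv,
                    evidence={
                        "n_events": len(best),
                        "organelle": best[0].organelle,
                    },
                )
            )
    return out
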
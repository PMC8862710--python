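"""Tandem-repeat monomer canonicalization and telomere/centromere calling.

Repeat finders report the monomer of a tandem array with an arbitrary
phase (start offset) and strand, so the same satellite family surfaces
under many different monomer strings and its genome-wide frequency is
split across them.  The fix used here is deterministic: every monomer is
replaced by its *canonical rotation* — the lexicographically smallest
string among all cyclic rotations of the monomer and of its reverse
complement — and frequencies are summed per canonical form.  Two
monomers describe the same family exactly when their canonical rotations
are equal, regardless of phase or strand.

On top of the canonical families sit the two placement callers:
telomere arrays (plant motif family TTTAGGG, canonical ``AAACCCT``) are
looked for within an end zone of each chromosome terminus, and
centromere candidates (satellite monomers of 79/80 bp) are located by an
exhaustive fixed-width window scan maximizing contained copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from .core import Genome, GenomicInterval, reverse_complement

logger = logging.getLogger(__name__)

MAX_MONOMER_LENGTH = 500

TELOMERE_MOTIF = "TTTAGGG"
TELOMERE_FAMILY = "AAACCCT"  # canonical rotation of TTTAGGG / CCCTAAA


@dataclass
class TandemRecord:
    """One tandem-array locus: genomic span, period, copies and monomer."""

    locus: GenomicInterval
    period: int
    copy_number: float
    monomer: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.monomer) <= MAX_MONOMER_LENGTH:
            raise ValueError(
                f"monomer length {len(self.monomer)} outside [1, {MAX_MONOMER_LENGTH}]"
            )
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")


@dataclass
class CanonicalMonomer:
    """A repeat family keyed by its rotation/strand canonical monomer."""

    canonical: str
    members: Set[str] = field(default_factory=set)
    total_frequency: float = 0.0

    @property
    def length(self) -> int:
        return len(self.canonical)


@dataclass
class TelomereCall:
    chrom: str
    end: str  # "left" | "right"
    present: bool
    array_span: Optional[GenomicInterval]
    array_bp: int


@dataclass
class CentromereCall:
    chrom: str
    main_cluster: Optional[GenomicInterval]
    copies_in_cluster: float
    scattered_copies: float
    monomer_family: Optional[str]


# ---------------------------------------------------------------------------
# Canonicalization


def _least_rotation_index(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    n2 = len(s2)
    f = [-1] * n2
    k = 0
    for j in range(1, n2):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def _least_rotation(s: str) -> str:
    k = _least_rotation_index(s)
    return (s + s)[k : k + len(s)]


def canonical_monomer(monomer: str) -> str:
    """Canonical form of a monomer across all rotations and both strands.

    Returns the lexicographic minimum over the ``2*len`` rotations of the
    monomer and of its reverse complement; idempotent by construction.
    """
    if not monomer:
        raise ValueError("empty monomer")
    monomer = monomer.upper()
    if set(monomer) - set("ACGT"):
        raise ValueError(
            f"non-ACGT symbol in monomer: {sorted(set(monomer) - set('ACGT'))}"
        )
    return min(_least_rotation(monomer), _least_rotation(reverse_complement(monomer)))


# ---------------------------------------------------------------------------
# TRF .dat parsing


def parse_trf_dat(path, max_period: int = MAX_MONOMER_LENGTH) -> List[TandemRecord]:
    """Parse a TRF ``.dat`` file into tandem records.

    The dialect: ``Sequence: <name>`` headers, optional ``Parameters:``
    lines, then space-separated records whose first four fields are
    start, end (1-based inclusive), period and copy number, with the
    consensus monomer as the 14th field (penultimate).  Records with a
    period above ``max_period`` are dropped with a logged count.
    """
    records: List[TandemRecord] = []
    chrom: Optional[str] = None
    dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(":", 1)[1].strip().split()[0]
                continue
            if line.startswith(("Parameters:", "Tandem", "Program", "Version", "Copyright", "#")):
                continue
            fields = line.split()
            if not fields[0].isdigit():
                continue
            if chrom is None:
                raise ValueError("TRF record before any 'Sequence:' header")
            start, end = int(fields[0]), int(fields[1])
            period = int(fields[2])
            copies = float(fields[3])
            monomer = fields[13] if len(fields) >= 14 else fields[-1]
            if period > max_period or len(monomer) > MAX_MONOMER_LENGTH:
                dropped += 1
                continue
            records.append(
                TandemRecord(
                    locus=GenomicInterval(chrom, start - 1, end),
                    period=period,
                    copy_number=copies,
                    monomer=monomer.upper(),
                )
            )
    if dropped:
        logger.info("parse_trf_dat: dropped %d records with period > %d", dropped, max_period)
    return records


def write_trf_dat(records_by_chrom: Dict[str, List[TandemRecord]], path) -> None:
    """Write tandem records in the TRF ``.dat`` dialect (inverse of the parser)."""
    with open(path, "w") as fh:
        fh.write("Tandem Repeats Finder Program written by a dat-dialect emitter\n\n")
        for chrom, records in records_by_chrom.items():
            fh.write(f"Sequence: {chrom}\n\n")
            fh.write("Parameters: 2 7 7 80 10 50 500\n\n")
            for r in records:
                comp = {b: round(100 * r.monomer.count(b) / len(r.monomer)) for b in "ACGT"}
                array = (r.monomer * (int(r.copy_number) + 2))[: r.locus.length]
                fh.write(
                    f"{r.locus.start + 1} {r.locus.end} {r.period} {r.copy_number:.1f} "
                    f"{r.period} 100 0 {2 * r.locus.length} "
                    f"{comp['A']} {comp['C']} {comp['G']} {comp['T']} 1.9 "
                    f"{r.monomer} {array}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Frequency merging


def merge_monomer_frequencies(
    records: Iterable[TandemRecord],
    approximate: bool = False,
    max_norm_edit_distance: float = 0.1,
) -> List[CanonicalMonomer]:
    """Merge copy-number frequencies of monomers that are the same family.

    Exact mode groups by canonical rotation/strand form and sums copy
    numbers, conserving total frequency.  The optional approximate mode
    additionally merges canonical forms of equal length whose normalized
    edit distance is at most ``max_norm_edit_distance``, absorbing
    near-identical variants (e.g. monomers carrying a point mutation)
    into the most frequent form.  Result is sorted by total frequency,
    descending (ties by canonical string for determinism).
    """
    families: Dict[str, CanonicalMonomer] = {}
    for rec in records:
        canon = canonical_monomer(rec.monomer)
        fam = families.setdefault(canon, CanonicalMonomer(canonical=canon))
        fam.members.add(rec.monomer)
        fam.total_frequency += rec.copy_number

    out = sorted(families.values(), key=lambda f: (-f.total_frequency, f.canonical))

    if approximate:
        merged: List[CanonicalMonomer] = []
        for fam in out:
            host = None
            for m in merged:
                if m.length != fam.length:
                    continue
                dist = edlib.align(fam.canonical, m.canonical, task="distance")["editDistance"]
                if dist / fam.length <= max_norm_edit_distance:
                    host = m
                    break
            if host is None:
                merged.append(fam)
            else:
                host.members |= fam.members
                host.total_frequency += fam.total_frequency
        out = sorted(merged, key=lambda f: (-f.total_frequency, f.canonical))
    return out


# ---------------------------------------------------------------------------
# Telomere calling


def call_telomeres(
    genome: Genome,
    records: Iterable[TandemRecord],
    motif_family: str = TELOMERE_FAMILY,
    end_zone: int = 100_000,
    min_array_bp: int = 1_000,
) -> List[TelomereCall]:
    """Call telomeric arrays at each chromosome end.

    Records whose canonical monomer equals ``motif_family`` and whose
    locus lies within ``end_zone`` of a terminus are merged per end; the
    end is called present iff the merged array totals at least
    ``min_array_bp``.
    """
    matching = [r for r in records if canonical_monomer(r.monomer) == motif_family]
    calls: List[TelomereCall] = []
    for chrom, length in genome.lengths.items():
        for end in ("left", "right"):
            if end == "left":
                in_zone = [
                    r for r in matching if r.locus.chrom == chrom and r.locus.start < end_zone
                ]
            else:
                in_zone = [
                    r
                    for r in matching
                    if r.locus.chrom == chrom and r.locus.end > length - end_zone
                ]
            array_bp = sum(r.locus.length for r in in_zone)
            span = None
            if in_zone:
                span = GenomicInterval(
                    chrom,
                    min(r.locus.start for r in in_zone),
                    max(r.locus.end for r in in_zone),
                )
            calls.append(
                TelomereCall(
                    chrom=chrom,
                    end=end,
                    present=array_bp >= min_array_bp,
                    array_span=span if array_bp >= min_array_bp else None,
                    array_bp=array_bp,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Centromere calling


def call_centromeres(
    records: Iterable[TandemRecord],
    monomer_lengths: Set[int] = frozenset({79, 80}),
    cluster_window: int = 1_000_000,
    chromosomes: Optional[Sequence[str]] = None,
) -> List[CentromereCall]:
    """Locate the main centromeric cluster per chromosome.

    Among records whose canonical monomer length is in
    ``monomer_lengths``, finds the ``cluster_window`` placement
    maximizing the contained copy number (a record counts by its start
    position; ties break leftmost).  Copies outside the chosen window
    are reported as scattered.  Chromosomes without candidate records
    get a call with ``main_cluster`` None.
    """
    candidates: Dict[str, List[TandemRecord]] = {}
    canon_cache: Dict[str, str] = {}
    for r in records:
        canon = canon_cache.setdefault(r.monomer, canonical_monomer(r.monomer))
        if len(canon) in monomer_lengths:
            candidates.setdefault(r.locus.chrom, []).append(r)

    chroms = list(chromosomes) if chromosomes is not None else sorted(candidates)
    calls: List[CentromereCall] = []
    for chrom in chroms:
        recs = sorted(candidates.get(chrom, []), key=lambda r: r.locus.start)
        if not recs:
            calls.append(CentromereCall(chrom, None, 0.0, 0.0, None))
            continue
        starts = np.array([r.locus.start for r in recs])
        copies = np.array([r.copy_number for r in recs])
        total = float(copies.sum())
        # Exhaustive scan over candidate window anchors (each record start):
        # the optimum is attained with the window's left edge at some record.
        best_sum, best_anchor, best_members = -1.0, 0, (0, 0)
        j = 0
        for i in range(len(recs)):
            while j < len(recs) and starts[j] < starts[i] + cluster_window:
                j += 1
            window_sum = float(copies[i:j].sum())
            if window_sum > best_sum:  # strict: ties keep the leftmost anchor
                best_sum, best_anchor, best_members = window_sum, i, (i, j)
        lo, hi = best_members
        cluster_recs = recs[lo:hi]
        cluster = GenomicInterval(
            chrom,
            min(r.locus.start for r in cluster_recs),
            max(r.locus.end for r in cluster_recs),
        )
        freq: Dict[str, float] = {}
        for r in cluster_recs:
            freq[canon_cache[r.monomer]] = freq.get(canon_cache[r.monomer], 0.0) + r.copy_number
        family = max(sorted(freq), key=lambda k: freq[k])
        calls.append(
            CentromereCall(
                chrom=chrom,
                main_cluster=cluster,
                copies_in_cluster=best_sum,
                scattered_copies=total - best_sum,
                monomer_family=family,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Exact tandem-array scan (internal stand-in for a repeat finder on
# synthetic, mutation-free arrays)


def find_exact_tandem_arrays(
    sequence: str,
    chrom: str = "seq",
    max_period: int = MAX_MONOMER_LENGTH,
    min_copies: float = 3.0,
) -> List[TandemRecord]:
    """Find maximal exact tandem arrays (``s[i] == s[i+p]`` runs).

    Arrays are reported with the smallest period explaining them and a
    copy count of ``run_length / period``; runs whose copy count falls
    below ``min_copies`` are dropped, and arrays interrupted by ``N``
    are split (``N`` never matches, not even itself).
    """
    sequence = sequence.upper()
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    found: List[TandemRecord] = []
    claimed: List[Tuple[int, int, int]] = []  # (start, end, period)
    for p in range(1, min(max_period, n // 2) + 1):
        eq = (arr[:-p] == arr[p:]) & ~is_n[:-p] & ~is_n[p:]
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.where(diff == 1)[0]
        run_ends = np.where(diff == -1)[0]
        for rs, re_ in zip(run_starts, run_ends):
            array_len = (re_ - rs) + p
            copies = array_len / p
            if copies < min_copies:
                continue
            start, end = int(rs), int(rs + array_len)
            # smallest-period rule: skip if contained in an array already
            # reported with a period dividing p
            if any(
                cs <= start and end <= ce and p % cp == 0
                for cs, ce, cp in claimed
            ):
                continue
            claimed.append((start, end, p))
            found.append(
                TandemRecord(
                    locus=GenomicInterval(chrom, start, end),
                    period=p,
                    copy_number=round(copies, 1),
                    monomer=sequence[start : start + p],
                )
            )
    found.sort(key=lambda r: (r.locus.start, r.period))
    return found
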
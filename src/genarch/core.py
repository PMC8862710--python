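"""Core domain types and coordinate conventions.

Every coordinate held in memory is 0-based and half-open ``[start, end)``.
The 1-based inclusive conventions of BLAST tabular output and VCF exist
only at the format boundary (:mod:`genarch.io`), which converts on read
and write.  Keeping a single internal convention removes the usual
off-by-one error class from all downstream interval arithmetic.

Sequences are stored upper-cased.  Lower-case letters and IUPAC
ambiguity codes other than ``N`` are treated as literal bases; only
maximal runs of ``N`` define assembly gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

_N_RUN = re.compile(r"N+")

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class Genome:
    """An ordered set of chromosome sequences with assembly-gap intervals.

    ``gaps`` lists maximal runs of ``N`` per chromosome, sorted and
    disjoint by construction.  This is the coordinate frame for every
    other annotation in the package.
    """

    sequences: Dict[str, str]
    gaps: List[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_sequences(cls, sequences: Dict[str, str]) -> "Genome":
        """Build a genome, upper-casing sequences and locating N-gaps."""
        upper = {name: seq.upper() for name, seq in sequences.items()}
        gaps = []
        for name, seq in upper.items():
            for m in _N_RUN.finditer(seq):
                gaps.append(GenomicInterval(name, m.start(), m.end()))
        return cls(sequences=upper, gaps=gaps)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> List[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def gaps_for(self, chrom: str) -> List[GenomicInterval]:
        return [g for g in self.gaps if g.chrom == chrom]


@dataclass
class WindowGrid:
    """Non-overlapping tiling of each chromosome into fixed-size windows.

    All windows have length ``window_size`` except the last one per
    chromosome, which holds the remainder.  The tail window is retained
    and downstream density metrics are reported as fractions of the
    actual window length.
    """

    window_size: int
    windows: Dict[str, List[GenomicInterval]]

    @classmethod
    def from_genome(cls, genome: Genome, window_size: int = 100_000) -> "WindowGrid":
        return make_window_grid(genome, window_size)

    @classmethod
    def from_lengths(cls, lengths: Dict[str, int], window_size: int = 100_000) -> "WindowGrid":
        if window_size <= 0:
            raise ValueError(f"window_size must be >= 1, got {window_size}")
        windows: Dict[str, List[GenomicInterval]] = {}
        for chrom, length in lengths.items():
            tiles = []
            for start in range(0, length, window_size):
                tiles.append(GenomicInterval(chrom, start, min(start + window_size, length)))
            windows[chrom] = tiles
        return cls(window_size=window_size, windows=windows)

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: (w[-1].end if w else 0) for c, w in self.windows.items()}

    def n_windows(self, chrom: Optional[str] = None) -> int:
        if chrom is not None:
            return len(self.windows[chrom])
        return sum(len(w) for w in self.windows.values())

    def window_index(self, chrom: str, pos: int) -> int:
        """Index (within the chromosome) of the window containing ``pos``."""
        if chrom not in self.windows:
            raise KeyError(f"unknown chromosome {chrom!r}")
        idx = pos // self.window_size
        if idx >= len(self.windows[chrom]):
            raise ValueError(f"position {pos} beyond end of {chrom}")
        return idx

    def window_range(self, iv: GenomicInterval) -> range:
        """Indices of all windows overlapped by ``iv`` (overlap rule)."""
        if iv.chrom not in self.windows:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        first = iv.start // self.window_size
        last = (iv.end - 1) // self.window_size
        last = min(last, len(self.windows[iv.chrom]) - 1)
        return range(first, last + 1)

    def iter_windows(self) -> Iterator[Tuple[str, int, GenomicInterval]]:
        for chrom, tiles in self.windows.items():
            for i, w in enumerate(tiles):
                yield chrom, i, w


def make_window_grid(genome: Genome, window_size: int = 100_000) -> WindowGrid:
    """Tile each chromosome ``[0, L)`` into ``ceil(L/window_size)`` windows."""
    return WindowGrid.from_lengths(genome.lengths, window_size)


@dataclass
class GeneModel:
    """A gene locus with exons and a multi-copy-family membership flag.

    The duplication flag marks membership of a multi-copy gene family;
    it is consumed as annotation (e.g. from a clustering run upstream),
    never computed here.
    """

    interval: GenomicInterval
    id: str
    exons: List[GenomicInterval] = field(default_factory=list)
    duplication_flag: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon {e} outside gene {self.id}")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"overlapping exons in gene {self.id}")
            prev_end = e.end


@dataclass
class AlignmentHit:
    """One organelle-to-nucleus alignment hit, coordinate-normalized.

    ``source_*`` is the span on the organelle genome, ``target`` the
    span on the nuclear assembly; both 0-based half-open with
    ``start < end`` and the original orientation recorded on
    ``target.strand``.
    """

    source_id: str
    source_start: int
    source_end: int
    target: GenomicInterval
    identity: float
    aln_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.source_start >= self.source_end:
            raise ValueError("source coordinates not normalized (start >= end)")


@dataclass
class PileupSite:
    """Per-position base counts for one individual."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in ("A", "C", "G", "T"):
            raise ValueError(f"ref_base must be one of ACGT, got {self.ref_base!r}")
        for base in "ACGT":
            self.counts.setdefault(base, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative base count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def merge_intervals(intervals: List[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: sorted, disjoint, per chromosome."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def coverage_per_window(
    intervals: List[GenomicInterval], grid: WindowGrid, chrom: str
) -> np.ndarray:
    """Covered base pairs per window of ``chrom`` (union of intervals)."""
    tiles = grid.windows[chrom]
    covered = np.zeros(len(tiles), dtype=np.int64)
    merged = merge_intervals([iv for iv in intervals if iv.chrom == chrom])
    for iv in merged:
        for wi in grid.window_range(iv):
            w = tiles[wi]
            covered[wi] += min(iv.end, w.end) - max(iv.start, w.start)
    return covered
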
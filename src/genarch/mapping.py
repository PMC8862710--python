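"""Mapping-population computations: segregation filtering and paternity.

Two independent pieces of pedigree machinery operate on a half-sib
progeny of a single mother tree.

The *four-step segregation filter* selects markers usable for a
maternal linkage map.  For a locus heterozygous in the mother and
monomorphic in the fathers, offspring genotypes segregate 1:1
heterozygote:homozygote, so the filter (1) demotes genotypes sequenced
below a depth floor to monomorphic, (2) keeps loci with at least half
the population heterozygous, (3) keeps loci whose het:hom ratio passes
a Pearson chi-square test against 1:1 using the printed critical value
6.635 (the upper 1% point of chi-square with 1 d.f.), and (4) keeps one
locus per contig — the one with fewest missing genotypes.

*Paternity assignment* uses Mendelian exclusion: given the mother's and
an offspring's genotypes, the set of possible paternal alleles at a
locus is determined, and a candidate father mismatches the locus when
none of his alleles can serve.  An offspring is assigned iff exactly
one candidate attains the minimum mismatch count and that minimum is
within ``max_mismatch`` (zero by default).  The mother herself may sit
among the candidates, covering self-pollination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CHI_SQ_1TO1_CRITICAL = 6.635  # printed critical value, chi-square 1 d.f.

HET, HOM, MISSING = "het", "hom", None


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype calls with per-call depths.

    ``genotypes``: DataFrame, index = locus ids, columns = individual
    ids, values in {"het", "hom", NaN}.  ``depths``: same shape,
    integer sequencing depth.  ``loci``: frame with columns
    ``contig`` and ``position`` indexed by locus id.
    """

    genotypes: pd.DataFrame
    depths: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.depths.index) or not list(
            self.genotypes.columns
        ) == list(self.depths.columns):
            raise ValueError("genotypes and depths must share index/columns")
        if not self.genotypes.index.equals(self.loci.index):
            raise ValueError("loci metadata must be indexed by the same locus ids")
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("negative depth")

    @property
    def individuals(self) -> List[str]:
        return list(self.genotypes.columns)

    @property
    def locus_ids(self) -> List[str]:
        return list(self.genotypes.index)

    def to_tsv(self, path) -> None:
        """Rows = loci (contig, position), columns = individuals, cells 'geno:depth'."""
        with open(path, "w") as fh:
            fh.write("locus\tcontig\tposition\t" + "\t".join(self.individuals) + "\n")
            for locus in self.genotypes.index:
                cells = []
                for ind in self.individuals:
                    g = self.genotypes.at[locus, ind]
                    d = int(self.depths.at[locus, ind])
                    cells.append(f"{'na' if pd.isna(g) else g}:{d}")
                fh.write(
                    f"{locus}\t{self.loci.at[locus, 'contig']}\t"
                    f"{int(self.loci.at[locus, 'position'])}\t" + "\t".join(cells) + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", comment=None)
        meta = df[["locus", "contig", "position"]].set_index("locus")
        inds = [c for c in df.columns if c not in ("locus", "contig", "position")]
        geno = pd.DataFrame(index=meta.index, columns=inds, dtype=object)
        depth = pd.DataFrame(0, index=meta.index, columns=inds, dtype=int)
        for _, row in df.iterrows():
            for ind in inds:
                g, d = str(row[ind]).split(":")
                geno.at[row["locus"], ind] = None if g == "na" else g
                depth.at[row["locus"], ind] = int(d)
        return cls(genotypes=geno, depths=depth, loci=meta)


@dataclass
class SegregationResult:
    retained_loci: List[str]
    per_step_counts: Tuple[int, int, int, int]
    chi_square: Dict[str, float]

    def summary(self) -> str:
        s1, s2, s3, s4 = self.per_step_counts
        return (
            f"four-step segregation filter: {s1} loci in; "
            f"{s2} after het-fraction step; {s3} after chi-square step; "
            f"{s4} retained (one per contig)"
        )


# ---------------------------------------------------------------------------
# Chi-square machinery


def chi_square_1to1(n_het: int, n_hom: int) -> float:
    """Pearson chi-square against a 1:1 het:hom ratio, no continuity correction."""
    total = n_het + n_hom
    if total < 1:
        raise ValueError("need at least one genotype")
    exp = total / 2.0
    return (n_het - exp) ** 2 / exp + (n_hom - exp) ** 2 / exp


def chi_square_critical(upper_tail: float = 0.01, df: int = 1) -> float:
    """Upper-tail critical value of the chi-square distribution."""
    return float(stats.chi2.ppf(1.0 - upper_tail, df))


# ---------------------------------------------------------------------------
# Four-step filter


def four_step_filter(
    m: GenotypeMatrix,
    min_depth: int = 20,
    min_het_fraction: float = 0.5,
    chi_sq_max: float = CHI_SQ_1TO1_CRITICAL,
    low_depth_to: str = "hom",
    het_fraction_denominator: str = "non_missing",
) -> SegregationResult:
    """Apply the four-step marker filter and return the retained loci.

    Step 1 reassigns heterozygous genotypes with depth below
    ``min_depth`` to homozygous ("set to monomorphic";
    ``low_depth_to='missing'`` selects the alternative reading).
    Step 2 keeps loci whose het fraction among non-missing genotypes is
    at least ``min_het_fraction`` (set
    ``het_fraction_denominator='all'`` for the absolute population
    reading).  Step 3 keeps loci with chi-square against 1:1 strictly
    below ``chi_sq_max``.  Step 4 keeps per contig the surviving locus
    with fewest missing genotypes, ties broken by smallest position.
    """
    if len(m.individuals) == 0:
        raise ValueError("genotype matrix has zero individuals")
    geno = m.genotypes.copy()
    low = (geno == HET) & (m.depths < min_depth)
    geno = geno.mask(low, HOM if low_depth_to == "hom" else np.nan)

    n_in = len(geno)
    chi: Dict[str, float] = {}
    survivors2: List[str] = []
    for locus in geno.index:
        row = geno.loc[locus]
        n_het = int((row == HET).sum())
        n_hom = int((row == HOM).sum())
        denom = (
            n_het + n_hom if het_fraction_denominator == "non_missing" else len(m.individuals)
        )
        if denom == 0:
            continue
        if n_het / denom >= min_het_fraction:
            survivors2.append(locus)
    survivors3: List[str] = []
    for locus in survivors2:
        row = geno.loc[locus]
        n_het = int((row == HET).sum())
        n_hom = int((row == HOM).sum())
        chi[locus] = chi_square_1to1(n_het, n_hom)
        if chi[locus] < chi_sq_max:
            survivors3.append(locus)

    missing_counts = geno.loc[survivors3].isna().sum(axis=1)
    retained: List[str] = []
    meta = m.loci.loc[survivors3]
    for contig, sub in meta.groupby("contig", sort=False):
        best = min(
            sub.index,
            key=lambda loc: (int(missing_counts[loc]), int(sub.at[loc, "position"])),
        )
        retained.append(best)
    retained.sort(key=lambda loc: (m.loci.at[loc, "contig"], int(m.loci.at[loc, "position"])))
    return SegregationResult(
        retained_loci=retained,
        per_step_counts=(n_in, len(survivors2), len(survivors3), len(retained)),
        chi_square=chi,
    )


# ---------------------------------------------------------------------------
# Paternity by Mendelian exclusion

Genotype = Optional[Tuple[str, str]]  # unordered allele pair or None


@dataclass
class MarkerGenotypes:
    """Diploid genotypes over a shared locus panel for one individual."""

    individual: str
    genotypes: Dict[str, Genotype]  # locus id -> allele pair (unordered) or None

    def __post_init__(self) -> None:
        for locus, g in self.genotypes.items():
            if g is not None and len(g) != 2:
                raise ValueError(f"{self.individual}@{locus}: genotype needs 2 alleles")


@dataclass
class PaternityAssignment:
    offspring: str
    assigned_father: Optional[str]
    mismatch_counts: Dict[str, int]
    status: str  # assigned | ambiguous | unassigned
    loci_used: int = 0


def _paternal_alleles(mother: Tuple[str, str], offspring: Tuple[str, str]) -> FrozenSet[str]:
    """Offspring alleles that can be of paternal origin given the mother.

    An offspring allele is a possible paternal allele when the *other*
    offspring allele could have come from the mother.  If the mother
    shares both offspring alleles, both are possible.
    """
    o1, o2 = offspring
    possible = set()
    if o2 in mother:
        possible.add(o1)
    if o1 in mother:
        possible.add(o2)
    return frozenset(possible)


def assign_father(
    offspring: MarkerGenotypes,
    mother: MarkerGenotypes,
    candidates: Sequence[MarkerGenotypes],
    max_mismatch: int = 0,
    allow_self: bool = True,
) -> PaternityAssignment:
    """Assign the father of one offspring by Mendelian exclusion.

    Loci where any of mother, offspring or the candidate is missing are
    skipped for that candidate; loci where the offspring is incompatible
    with the mother (no possible paternal allele) are skipped with a
    warning, as they indicate a genotyping error rather than paternity
    evidence.  With ``allow_self`` the mother may appear among the
    candidates (self-pollination).
    """
    cands = list(candidates)
    if not allow_self:
        cands = [c for c in cands if c.individual != mother.individual]
    mismatches: Dict[str, int] = {}
    loci_used_max = 0
    for cand in cands:
        n_mm = 0
        used = 0
        for locus, off_g in offspring.genotypes.items():
            mom_g = mother.genotypes.get(locus)
            cand_g = cand.genotypes.get(locus)
            if off_g is None or mom_g is None or cand_g is None:
                continue
            paternal = _paternal_alleles(mom_g, off_g)
            if not paternal:
                continue  # mother-offspring incompatibility; not paternal evidence
            used += 1
            if not (set(cand_g) & paternal):
                n_mm += 1
        mismatches[cand.individual] = n_mm
        loci_used_max = max(loci_used_max, used)
    if not mismatches or loci_used_max == 0:
        logger.warning("assign_father(%s): no shared informative loci", offspring.individual)
        return PaternityAssignment(offspring.individual, None, mismatches, "unassigned", 0)
    best = min(mismatches.values())
    at_best = [c for c, n in mismatches.items() if n == best]
    if best > max_mismatch:
        status, father = "unassigned", None
    elif len(at_best) > 1:
        status, father = "ambiguous", None
    else:
        status, father = "assigned", at_best[0]
    return PaternityAssignment(offspring.individual, father, mismatches, status, loci_used_max)


def assign_paternity(
    offspring_set: Iterable[MarkerGenotypes],
    mother: MarkerGenotypes,
    candidates: Sequence[MarkerGenotypes],
    max_mismatch: int = 0,
    allow_self: bool = True,
) -> List[PaternityAssignment]:
    return [
        assign_father(o, mother, candidates, max_mismatch=max_mismatch, allow_self=allow_self)
        for o in offspring_set
    ]


# ---------------------------------------------------------------------------
# Summary arithmetic


def family_summary(assignments: Iterable[PaternityAssignment]) -> Tuple[pd.Series, int]:
    """Full-sib family sizes per assigned father, and their total."""
    counts: Dict[str, int] = {}
    for a in assignments:
        if a.status == "assigned" and a.assigned_father is not None:
            counts[a.assigned_father] = counts.get(a.assigned_father, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    return series, int(series.sum()) if len(series) else 0


def map_summary(
    per_lg_sizes_cm: Sequence[float], per_lg_marker_counts: Sequence[int]
) -> Tuple[float, int]:
    """Total genetic size (cM) and total marker count over linkage groups."""
    if len(per_lg_sizes_cm) != len(per_lg_marker_counts):
        raise ValueError(
            f"length mismatch: {len(per_lg_sizes_cm)} sizes vs "
            f"{len(per_lg_marker_counts)} marker counts"
        )
    return float(sum(per_lg_sizes_cm)), int(sum(per_lg_marker_counts))


# ---------------------------------------------------------------------------
# Marker-panel TSV (mother / candidates / offspring)


def write_marker_tsv(individuals: Iterable[MarkerGenotypes], roles: Dict[str, str], path) -> None:
    """One row per individual: id, role, then 'A/B' genotypes per locus."""
    individuals = list(individuals)
    loci = list(individuals[0].genotypes) if individuals else []
    with open(path, "w") as fh:
        fh.write("id\trole\t" + "\t".join(loci) + "\n")
        for ind in individuals:
            cells = []
            for locus in loci:
                g = ind.genotypes.get(locus)
                cells.append("-" if g is None else f"{g[0]}/{g[1]}")
            fh.write(f"{ind.individual}\t{roles.get(ind.individual, 'candidate')}\t" + "\t".join(cells) + "\n")


def read_marker_tsv(path) -> Tuple[List[MarkerGenotypes], Dict[str, str]]:
    inds: List[MarkerGenotypes] = []
    roles: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        loci = header[2:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ind, role = fields[0], fields[1]
            genos: Dict[str, Genotype] = {}
            for locus, cell in zip(loci, fields[2:]):
                genos[locus] = None if cell == "-" else tuple(cell.split("/"))  # type: ignore[assignment]
            inds.append(MarkerGenotypes(individual=ind, genotypes=genos))
            roles[ind] = role
    return inds, roles
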
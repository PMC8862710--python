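"""Segregation filtering, Mendelian-exclusion paternity, summary arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genarch.mapping import (
    GenotypeMatrix,
    MarkerGenotypes,
    assign_father,
    assign_paternity,
    chi_square_1to1,
    chi_square_critical,
    family_summary,
    four_step_filter,
    map_summary,
)
from genarch.simulate import (
    MappingPlan,
    PaternityPlan,
    simulate_genotype_matrix,
    simulate_paternity_panel,
)

# Published pedigree-reconstruction family sizes and linkage-group summary
# rows used as worked-example inputs for the summary arithmetic.
FAMILY_SIZES = {
    "MSSB": 47, "MSSH": 68, "SSP01": 24, "SSP02": 27, "SSP03": 4, "SSP04": 10,
    "SSP05": 16, "SSP06": 13, "SSP07": 9, "SSP08": 17, "SSP09": 12, "SSP10": 9,
    "SSP11": 17, "SSP12": 86, "SSP13": 15, "SSP14": 10, "SSP15": 2, "SSP16": 13,
    "SSP17": 3, "SSP18": 8,
}
LG_SIZES_CM = [279, 152, 224, 137, 168, 192, 146, 172, 182, 171, 186, 64, 140]
LG_MARKER_COUNTS = [37, 30, 56, 36, 49, 24, 24, 22, 29, 15, 22, 16, 8]


class TestChiSquare:
    def test_perfect_ratio_is_zero(self):
        assert chi_square_1to1(100, 100) == 0.0

    def test_distorted_ratio(self):
        assert chi_square_1to1(130, 70) == 18.0

    def test_mild_ratio_passes_critical_value(self):
        assert chi_square_1to1(60, 40) == 4.0
        assert chi_square_1to1(60, 40) < 6.635

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            chi_square_1to1(0, 0)

    def test_critical_value_upper_one_percent(self):
        assert round(chi_square_critical(0.01, 1), 3) == 6.635

    def test_agrees_with_generic_pearson_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1_000):
            n_het = int(rng.integers(0, 300))
            n_hom = int(rng.integers(0, 300))
            if n_het + n_hom == 0:
                continue
            expected = stats.chisquare([n_het, n_hom]).statistic
            assert chi_square_1to1(n_het, n_hom) == pytest.approx(expected)


def _matrix(loci):
    """Build a GenotypeMatrix from {locus: (contig, pos, genotypes, depths)}."""
    inds = [f"i{k}" for k in range(len(next(iter(loci.values()))[2]))]
    geno = pd.DataFrame(
        {ind: [loci[l][2][k] for l in loci] for k, ind in enumerate(inds)},
        index=list(loci), dtype=object,
    )
    depth = pd.DataFrame(
        {ind: [loci[l][3][k] for l in loci] for k, ind in enumerate(inds)},
        index=list(loci),
    )
    meta = pd.DataFrame(
        {"contig": [loci[l][0] for l in loci], "position": [loci[l][1] for l in loci]},
        index=list(loci),
    )
    return GenotypeMatrix(geno, depth, meta)


class TestFourStepFilter:
    def test_low_het_fraction_removed_at_step_two(self):
        g = ["het"] * 4 + ["hom"] * 6
        m = _matrix({"l1": ("c1", 10, g, [30] * 10)})
        res = four_step_filter(m)
        assert res.retained_loci == [] and res.per_step_counts == (1, 0, 0, 0)

    def test_distorted_locus_removed_at_step_three(self):
        g = ["het"] * 130 + ["hom"] * 70
        m = _matrix({"l1": ("c1", 10, g, [30] * 200)})
        res = four_step_filter(m)
        assert res.per_step_counts == (1, 1, 0, 0)
        assert res.chi_square["l1"] == 18.0

    def test_low_depth_het_demoted_to_hom(self):
        # 6 het / 4 hom passes as-is; demoting two het calls at depth 19
        # tips the het fraction to 4/10 and the locus is lost at step two
        g = ["het"] * 6 + ["hom"] * 4
        d = [19, 19] + [30] * 8
        res = four_step_filter(_matrix({"l1": ("c1", 10, g, d)}))
        assert res.per_step_counts == (1, 0, 0, 0)
        res2 = four_step_filter(_matrix({"l1": ("c1", 10, g, [30] * 10)}))
        assert res2.retained_loci == ["l1"]

    def test_low_depth_to_missing_interpretation(self):
        # under the missing reading the same matrix keeps the locus:
        # 4 het of 8 non-missing is exactly the half threshold
        g = ["het"] * 6 + ["hom"] * 4
        d = [19, 19] + [30] * 8
        res = four_step_filter(_matrix({"l1": ("c1", 10, g, d)}), low_depth_to="missing")
        assert res.retained_loci == ["l1"]

    def test_fewest_missing_kept_per_contig(self):
        g_a = ["het"] * 5 + ["hom"] * 5 + [None] * 3
        g_b = ["het"] * 5 + ["hom"] * 3 + [None] * 5
        m = _matrix({
            "a": ("c1", 500, g_a, [30] * 13),
            "b": ("c1", 100, g_b, [30] * 13),
        })
        res = four_step_filter(m)
        assert res.retained_loci == ["a"]  # 3 missing beats 5 despite position

    def test_tie_on_missing_breaks_by_position(self):
        g = ["het"] * 5 + ["hom"] * 5
        m = _matrix({
            "far": ("c1", 900, g, [30] * 10),
            "near": ("c1", 100, g, [30] * 10),
        })
        res = four_step_filter(m)
        assert res.retained_loci == ["near"]

    def test_zero_individuals_error(self):
        geno = pd.DataFrame(index=["l1"], dtype=object)
        depth = pd.DataFrame(index=["l1"])
        meta = pd.DataFrame({"contig": ["c1"], "position": [1]}, index=["l1"])
        with pytest.raises(ValueError, match="zero individuals"):
            four_step_filter(GenotypeMatrix(geno, depth, meta))

    def test_planted_one_to_one_set_recovered(self):
        m, classes, planted = simulate_genotype_matrix(MappingPlan(), 23)
        res = four_step_filter(m)
        assert sorted(res.retained_loci) == sorted(planted)
        s1, s2, s3, s4 = res.per_step_counts
        assert s1 >= s2 >= s3 >= s4  # monotone filtering

    def test_filter_is_idempotent_on_retained_set(self):
        m, _, _ = simulate_genotype_matrix(MappingPlan(n_contigs=10), 23)
        res = four_step_filter(m)
        sub = GenotypeMatrix(
            m.genotypes.loc[res.retained_loci],
            m.depths.loc[res.retained_loci],
            m.loci.loc[res.retained_loci],
        )
        assert four_step_filter(sub).retained_loci == res.retained_loci


def _mk(ind, **genos):
    return MarkerGenotypes(individual=ind,
                           genotypes={k: tuple(v) if v else None for k, v in genos.items()})


class TestAssignFather:
    def test_mendelian_exclusion_basic(self):
        mother = _mk("M", l1="AA")
        offspring = _mk("o", l1="AB")
        bb, aa = _mk("BB", l1="BB"), _mk("AA", l1="AA")
        res = assign_father(offspring, mother, [bb, aa])
        assert res.assigned_father == "BB" and res.status == "assigned"
        assert res.mismatch_counts == {"BB": 0, "AA": 1}

    def test_shared_heterozygote_allows_both_alleles(self):
        mother = _mk("M", l1="AB")
        offspring = _mk("o", l1="AB")
        cc = _mk("CC", l1="CC")
        ab = _mk("F", l1="AB")
        res = assign_father(offspring, mother, [cc, ab])
        assert res.mismatch_counts == {"CC": 1, "F": 0}

    def test_two_zero_mismatch_candidates_ambiguous(self):
        mother = _mk("M", l1="AA")
        offspring = _mk("o", l1="AB")
        res = assign_father(offspring, mother, [_mk("F1", l1="BB"), _mk("F2", l1="AB")])
        assert res.status == "ambiguous" and res.assigned_father is None

    def test_no_shared_loci_unassigned(self):
        res = assign_father(_mk("o", l1=None), _mk("M", l1="AA"), [_mk("F", l1="AA")])
        assert res.status == "unassigned"

    def test_selfing_mother_can_be_assigned(self):
        mother = _mk("M", l1="AB", l2="AA")
        offspring = _mk("o", l1="AA", l2="AA")
        other = _mk("F", l1="BB", l2="BB")
        res = assign_father(offspring, mother, [mother, other], allow_self=True)
        assert res.assigned_father == "M"
        res2 = assign_father(offspring, mother, [mother, other], allow_self=False)
        assert res2.status == "unassigned"

    def test_perfect_recovery_at_zero_error(self):
        panel, roles, fathers = simulate_paternity_panel(PaternityPlan(), 31)
        mother = next(p for p in panel if roles[p.individual] == "mother")
        cands = [p for p in panel if roles[p.individual] in ("mother", "candidate")]
        offspring = [p for p in panel if roles[p.individual] == "offspring"]
        assignments = assign_paternity(offspring, mother, cands)
        assert all(a.status == "assigned" for a in assignments)
        assert all(a.assigned_father == fathers[a.offspring] for a in assignments)
        assert all(a.loci_used >= 20 for a in assignments)

    def test_errors_never_cause_misassignment(self):
        misassigned = 0
        for seed in (1, 2, 3):
            panel, roles, fathers = simulate_paternity_panel(
                PaternityPlan(error_rate=0.1), seed)
            mother = next(p for p in panel if roles[p.individual] == "mother")
            cands = [p for p in panel if roles[p.individual] in ("mother", "candidate")]
            offspring = [p for p in panel if roles[p.individual] == "offspring"]
            for a in assign_paternity(offspring, mother, cands):
                if a.status == "assigned" and a.assigned_father != fathers[a.offspring]:
                    misassigned += 1
        assert misassigned == 0

    def test_unassigned_fraction_monotone_in_error_rate(self):
        fractions = []
        for error in (0.0, 0.1, 0.3):
            unassigned = 0
            total = 0
            for seed in (5, 6, 7):
                panel, roles, _ = simulate_paternity_panel(
                    PaternityPlan(error_rate=error), seed)
                mother = next(p for p in panel if roles[p.individual] == "mother")
                cands = [p for p in panel
                         if roles[p.individual] in ("mother", "candidate")]
                offspring = [p for p in panel if roles[p.individual] == "offspring"]
                res = assign_paternity(offspring, mother, cands)
                unassigned += sum(1 for a in res if a.status != "assigned")
                total += len(res)
            fractions.append(unassigned / total)
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[0] == 0.0 and fractions[2] > 0.0


class TestSummaries:
    def test_family_summary_over_published_sizes(self):
        from genarch.mapping import PaternityAssignment

        assignments = [
            PaternityAssignment(f"{father}_{k}", father, {father: 0}, "assigned")
            for father, size in FAMILY_SIZES.items()
            for k in range(size)
        ]
        families, total = family_summary(assignments)
        assert total == 410
        assert families["SSP12"] == 86 and families["MSSH"] == 68

    def test_family_summary_empty(self):
        families, total = family_summary([])
        assert len(families) == 0 and total == 0

    def test_family_summary_single_father(self):
        from genarch.mapping import PaternityAssignment

        assignments = [PaternityAssignment(f"o{k}", "F1", {"F1": 0}, "assigned")
                       for k in range(3)]
        families, total = family_summary(assignments)
        assert families.to_dict() == {"F1": 3} and total == 3

    def test_map_summary_totals(self):
        total_cm, total_markers = map_summary(LG_SIZES_CM, LG_MARKER_COUNTS)
        assert total_cm == 2_213
        assert total_markers == 368

    def test_map_summary_empty(self):
        assert map_summary([], []) == (0.0, 0)

    def test_map_summary_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            map_summary([1.0, 2.0], [3])


class TestGenotypeMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        m, _, _ = simulate_genotype_matrix(
            MappingPlan(n_offspring=12, n_contigs=3, missing_rate=0.1), 2)
        m.to_tsv(tmp_path / "g.tsv")
        back = GenotypeMatrix.from_tsv(tmp_path / "g.tsv")
        assert back.individuals == m.individuals
        assert back.locus_ids == m.locus_ids
        for locus in m.locus_ids:
            for ind in m.individuals:
                a, b = m.genotypes.at[locus, ind], back.genotypes.at[locus, ind]
                assert (pd.isna(a) and pd.isna(b)) or a == b
        pd.testing.assert_frame_equal(back.depths, m.depths, check_names=False)
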
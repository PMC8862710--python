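"""Allele-balance classification and windowed SNP landscape screens."""

import numpy as np
import pandas as pd
import pytest

from genarch.core import GeneModel, GenomicInterval, PileupSite, WindowGrid
from genarch.snp import (
    SnpCall,
    SnpWindowProfile,
    call_inter_individual,
    classify_pileup,
    classify_site,
    detect_decoupled_windows,
    detect_low_het_regions,
    detect_repeat_gene_anomalies,
    profile_snp_windows,
    repeat_fraction_profile,
    window_count_histogram,
)


def _site(ref_n, alt_n, ref="A", alt="G", chrom="c", pos=1000):
    return PileupSite(chrom, pos, ref, {ref: ref_n, alt: alt_n})


class TestClassifySite:
    def test_balanced_site_is_heterozygous(self):
        call = classify_site(_site(5, 5))
        assert call.state == "heterozygous" and call.alt_fraction == 0.5

    def test_depth_below_ten_is_no_call(self):
        call = classify_site(_site(5, 4))
        assert (call.state, call.reason) == ("no_call", "low_depth")

    def test_depth_zero_is_no_call(self):
        call = classify_site(_site(0, 0))
        assert (call.state, call.reason) == ("no_call", "low_depth")

    def test_alt_dominated_site_is_homozygous_alt(self):
        call = classify_site(_site(4, 16))
        assert call.state == "homozygous_alt" and call.alt_fraction == 0.8

    def test_near_gap_is_no_call(self):
        gaps = [GenomicInterval("c", 1002, 1010)]
        call = classify_site(_site(5, 5), gaps=gaps)
        assert (call.state, call.reason) == ("no_call", "near_gap")
        downstream = classify_site(_site(5, 5, pos=1012), gaps=gaps)
        assert downstream.reason == "near_gap"
        clear = classify_site(_site(5, 5, pos=1013), gaps=gaps)
        assert clear.state == "heterozygous"

    @pytest.mark.parametrize(
        "ref_n,alt_n,state",
        [
            (15, 5, "heterozygous"),      # 0.25 inclusive lower bound
            (16, 4, "reference"),         # 0.20 below the band
            (5, 15, "homozygous_alt"),    # 0.75 inclusive upper bound
            (2501, 7499, "heterozygous"), # 0.7499 just under the bound
        ],
    )
    def test_half_open_threshold_boundaries(self, ref_n, alt_n, state):
        assert classify_site(_site(ref_n, alt_n)).state == state

    def test_multiallelic_pools_all_non_reference(self):
        site = PileupSite("c", 0, "A", {"A": 10, "C": 5, "G": 5, "T": 0})
        call = classify_site(site)
        assert call.state == "heterozygous" and call.alt_fraction == 0.5
        assert call.alt_base in ("C", "G")

    def test_alt_ref_ratio_mode_is_selectable(self):
        # 10 ref / 10 alt: alt/ref = 1.0 >= 0.75 -> homozygous under the
        # literal reading, heterozygous under the fraction reading
        assert classify_site(_site(10, 10), ratio_mode="alt_ref").state == "homozygous_alt"
        assert classify_site(_site(10, 10)).state == "heterozygous"

    def test_classification_is_a_partition(self, default_calls):
        states = pd.Series([c.state for c in default_calls]).value_counts()
        assert states.sum() == len(default_calls)
        assert set(states.index) <= {"heterozygous", "homozygous_alt", "reference", "no_call"}

    def test_planted_states_recovered(self, default_sim, default_calls):
        truth = default_sim.truth.snp_sites.set_index(["chrom", "pos"])["true_state"]
        by_pos = {(c.chrom, c.pos): c for c in default_calls}
        het = truth[truth == "het"]
        calls = [by_pos[k] for k in het.index]
        eligible = [c for c in calls if c.depth >= 10]
        rate = np.mean([c.state == "heterozygous" for c in eligible])
        assert rate >= 0.99
        for key in truth[truth == "near_gap"].index:
            assert by_pos[key].reason == "near_gap"
        for key in truth[truth == "hom_alt"].index:
            assert by_pos[key].state == "homozygous_alt"


class TestInterIndividual:
    def _call(self, state, ref="A", alt="G", pos=10):
        frac = {"heterozygous": 0.5, "homozygous_alt": 0.9, "reference": 0.0}[state]
        return SnpCall("c", pos, ref, state, frac, alt_base=alt, depth=30)

    def test_homozygous_alt_vs_different_consensus(self):
        (snp,) = call_inter_individual([self._call("homozygous_alt")], {("c", 10): "T"})
        assert snp.kind == "homozygous_diff" and snp.basis == "T"

    def test_reference_vs_different_consensus(self):
        (snp,) = call_inter_individual([self._call("reference")], {("c", 10): "C"})
        assert snp.basis == "C"

    def test_matching_consensus_not_emitted(self):
        assert call_inter_individual([self._call("reference")], {("c", 10): "A"}) == []
        assert call_inter_individual([self._call("homozygous_alt")], {("c", 10): "G"}) == []

    def test_heterozygous_first_individual_not_emitted(self):
        assert call_inter_individual([self._call("heterozygous")], {("c", 10): "T"}) == []

    def test_non_acgt_consensus_skipped(self):
        assert call_inter_individual([self._call("reference")], {("c", 10): "N"}) == []


def _profile_from_counts(het, hom=None, genic_het=None, genic_hom=None, gene_fraction=0.15,
                         window=100_000):
    n = len(het)
    hom = hom if hom is not None else [0] * n
    genic_het = genic_het if genic_het is not None else [0] * n
    genic_hom = genic_hom if genic_hom is not None else [0] * n
    gf = gene_fraction if isinstance(gene_fraction, list) else [gene_fraction] * n
    table = pd.DataFrame(
        {
            "chrom": ["c"] * n,
            "start": [i * window for i in range(n)],
            "end": [(i + 1) * window for i in range(n)],
            "het_count": het,
            "hom_count": hom,
            "genic_het": genic_het,
            "genic_hom": genic_hom,
            "intergenic_het": [h - g for h, g in zip(het, genic_het)],
            "intergenic_hom": [h - g for h, g in zip(hom, genic_hom)],
            "gene_fraction": gf,
        }
    )
    grid = WindowGrid.from_lengths({"c": n * window}, window)
    return SnpWindowProfile(grid=grid, table=table)


class TestProfileWindows:
    GRID = WindowGrid.from_lengths({"c": 300_000}, 100_000)

    def _calls(self, positions, state="heterozygous"):
        return [SnpCall("c", p, "A", state, 0.5, depth=30) for p in positions]

    def test_counts_and_genic_split(self):
        genes = [GeneModel(GenomicInterval("c", 10_000, 20_000), "g1")]
        profile = profile_snp_windows(
            self._calls([5_000, 15_000, 50_000]), [], genes, self.GRID
        )
        row = profile.table.iloc[0]
        assert (row["het_count"], row["genic_het"], row["intergenic_het"]) == (3, 1, 2)

    def test_empty_window_is_zero(self):
        profile = profile_snp_windows([], [], [], self.GRID)
        assert (profile.table[["het_count", "hom_count"]].to_numpy() == 0).all()

    def test_gene_boundary_start_is_genic_end_is_not(self):
        genes = [GeneModel(GenomicInterval("c", 10_000, 20_000), "g1")]
        profile = profile_snp_windows(
            self._calls([10_000, 20_000]), [], genes, self.GRID
        )
        assert profile.table.iloc[0]["genic_het"] == 1  # half-open containment

    def test_window_conservation_on_simulation(
        self, default_calls, default_inter, default_genes, default_grid
    ):
        profile = profile_snp_windows(default_calls, default_inter, default_genes,
                                      default_grid)
        t = profile.table
        n_het = sum(1 for c in default_calls if c.state == "heterozygous")
        assert t["het_count"].sum() == n_het
        assert t["hom_count"].sum() == len(default_inter)
        assert (t["genic_het"] + t["intergenic_het"]).equals(t["het_count"])
        assert (t["genic_hom"] + t["intergenic_hom"]).equals(t["hom_count"])


class TestLowHetRegions:
    def test_planted_desert_detected_extended(
        self, default_sim, default_calls, default_inter, default_genes, default_grid
    ):
        profile = profile_snp_windows(default_calls, default_inter, default_genes,
                                      default_grid)
        regions = detect_low_het_regions(profile)
        truth = default_sim.truth.low_het_regions[0]
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.chrom, r.interval.start, r.interval.end) == (
            truth["chrom"], truth["start"], truth["stop"])
        assert r.extended and r.type == "low_het"  # hom stays high in the desert

    def test_uniform_profile_empty(self):
        profile = _profile_from_counts([50] * 200, hom=[25] * 200)
        assert detect_low_het_regions(profile) == []

    def test_short_low_run_with_high_hom_is_low_het_not_low_both(self):
        het = [50] * 100
        hom = [25] * 100
        for i in range(40, 52):  # 1.2 Mb of empty het windows, elevated hom
            het[i] = 0
            hom[i] = 60
        regions = detect_low_het_regions(_profile_from_counts(het, hom))
        (r,) = regions
        assert r.type == "low_het" and not r.extended
        assert (r.interval.start, r.interval.end) == (4_000_000, 5_200_000)

    def test_low_both_when_hom_also_depressed(self):
        het = [50] * 100
        hom = [25] * 100
        for i in range(40, 52):
            het[i] = 0
            hom[i] = 0
        (r,) = detect_low_het_regions(_profile_from_counts(het, hom))
        assert r.type == "low_both"

    def test_insufficient_windows_error(self):
        with pytest.raises(ValueError, match="insufficient windows"):
            detect_low_het_regions(_profile_from_counts([5] * 9))


class TestDecoupledWindows:
    def test_high_intergenic_zero_genic_reported(self):
        het = [50] * 40 + [200]
        genic = [8] * 40 + [0]
        profile = _profile_from_counts(het, hom=[25] * 41, genic_het=genic)
        (r,) = detect_decoupled_windows(profile)
        assert r.interval.start == 40 * 100_000
        assert r.stats["kind"] == "conserved"

    def test_window_without_genes_never_reported(self):
        het = [50] * 40 + [200]
        genic = [8] * 40 + [0]
        gf = [0.15] * 40 + [0.0]
        profile = _profile_from_counts(het, hom=[25] * 41, genic_het=genic,
                                       gene_fraction=gf)
        assert detect_decoupled_windows(profile) == []

    def test_uniform_profile_empty(self):
        profile = _profile_from_counts([50] * 50, hom=[25] * 50, genic_het=[8] * 50,
                                       genic_hom=[4] * 50)
        assert detect_decoupled_windows(profile) == []

    def test_homozygous_mirror_case_reported(self):
        hom = [25] * 40 + [2]
        genic_hom = [4] * 40 + [20]
        profile = _profile_from_counts([50] * 41, hom=hom, genic_hom=genic_hom)
        (r,) = detect_decoupled_windows(profile)
        assert r.stats["kind"] == "diversifying"


class TestHistogram:
    def test_single_bin_mass(self):
        profile = _profile_from_counts([5] * 10, hom=[5] * 10)
        hist = window_count_histogram(profile, bins=[0, 10, 20])
        assert hist["het_windows"].tolist() == [10, 0]

    def test_empty_profile(self):
        profile = _profile_from_counts([])
        assert len(window_count_histogram(profile)) == 0

    def test_het_and_hom_histograms_conserve_window_total(self, default_calls,
                                                          default_inter, default_genes,
                                                          default_grid):
        profile = profile_snp_windows(default_calls, default_inter, default_genes,
                                      default_grid)
        hist = window_count_histogram(profile)
        assert hist["het_windows"].sum() == len(profile.table)
        assert hist["hom_windows"].sum() == len(profile.table)


class TestRepeatGeneAnomalies:
    def test_planted_regions_recovered(self, default_sim, default_genes, default_grid):
        from genarch import io as gio

        repeat_iv = [iv for iv, _ in gio.read_regions_bed(default_sim.paths["repeats_bed"])]
        rprofile = repeat_fraction_profile(repeat_iv, default_grid)
        regions = detect_repeat_gene_anomalies(rprofile, default_genes, default_grid)
        rich = [r for r in regions if r.type == "repeat_rich"]
        dup = [r for r in regions if r.type == "dup_gene_cluster"]
        truth_rich = default_sim.truth.repeat_rich[0]
        assert len(rich) == 1
        assert (rich[0].interval.start, rich[0].interval.end) == (
            truth_rich["start"], truth_rich["stop"])
        assert rich[0].stats["fraction_above"] >= 0.9
        truth_dup = default_sim.truth.dup_gene_clusters[0]
        assert len(dup) == 1
        assert dup[0].interval.overlaps(
            GenomicInterval(truth_dup["chrom"], truth_dup["start"], truth_dup["stop"]))

    def test_dup_cluster_above_threshold_reported(self):
        grid = WindowGrid.from_lengths({"c": 4_000_000}, 100_000)
        genes = []
        for i, start in enumerate(range(5_000, 3_990_000, 20_000)):
            in_cluster = 1_000_000 <= start < 2_500_000
            genes.append(GeneModel(
                GenomicInterval("c", start, start + 3_000), f"g{i}",
                duplication_flag=in_cluster and i % 5 < 2))
        rprofile = repeat_fraction_profile([], grid)
        regions = detect_repeat_gene_anomalies(rprofile, genes, grid)
        (r,) = regions
        assert r.type == "dup_gene_cluster"
        assert r.interval.overlaps(GenomicInterval("c", 1_000_000, 2_500_000))

    def test_homogeneous_genome_empty(self, feature_free_sim):
        from genarch import io as gio

        g = gio.read_fasta(feature_free_sim.paths["genome_fasta"])
        grid = WindowGrid.from_genome(g)
        genes = gio.read_genes_gff3(feature_free_sim.paths["genes_gff3"])
        repeat_iv = [iv for iv, _ in gio.read_regions_bed(feature_free_sim.paths["repeats_bed"])]
        rprofile = repeat_fraction_profile(repeat_iv, grid)
        assert detect_repeat_gene_anomalies(rprofile, genes, grid) == []
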
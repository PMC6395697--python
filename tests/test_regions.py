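import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.stats import chi2

from methylscape.regions import (
    annotate_lmr_position,
    call_group_specific_lmrs,
    enhancer_overlap_ratio,
    jaccard_sample_clustering,
    linkage_to_newick,
    profile_and_cluster_lmrs,
    SpecificRegionSet,
)
from methylscape.types import GeneModel, GenomicInterval, Segment

from conftest import make_sample


def lmr(start, end, chrom="chrS"):
    return Segment(GenomicInterval(chrom, start, end), "LMR", 5, 0.2)


GROUPS6 = {
    "RA_01": "RA", "RA_02": "RA", "RA_03": "RA",
    "OA_01": "OA", "OA_02": "OA", "OA_03": "OA",
}


class TestSpecificLmrs:
    def base(self):
        return {sid: [] for sid in GROUPS6}

    def test_three_ra_zero_oa_is_ra_specific(self):
        lmrs = self.base()
        for sid in ("RA_01", "RA_02", "RA_03"):
            lmrs[sid] = [lmr(1000, 1500)]
        ra, oa = call_group_specific_lmrs(lmrs, GROUPS6)
        assert len(ra) == 1 and len(oa) == 0
        assert ra.support.iloc[0]["n_ra_detected"] == 3
        assert ra.support.iloc[0]["n_oa_detected"] == 0

    def test_any_other_group_detection_rejects(self):
        lmrs = self.base()
        for sid in ("RA_01", "RA_02", "RA_03"):
            lmrs[sid] = [lmr(1000, 1500)]
        lmrs["OA_01"] = [lmr(1400, 1600)]  # overlaps the consensus
        ra, oa = call_group_specific_lmrs(lmrs, GROUPS6)
        assert len(ra) == 0 and len(oa) == 0

    def test_two_supporting_samples_insufficient(self):
        lmrs = self.base()
        for sid in ("RA_01", "RA_02"):
            lmrs[sid] = [lmr(1000, 1500)]
        ra, _ = call_group_specific_lmrs(lmrs, GROUPS6)
        assert len(ra) == 0

    def test_abutting_sample_calls_are_not_merged(self):
        lmrs = self.base()
        lmrs["RA_01"] = [lmr(1000, 1500)]
        lmrs["RA_02"] = [lmr(1500, 2000)]  # touches, no shared base
        lmrs["RA_03"] = [lmr(1000, 1500)]
        ra, _ = call_group_specific_lmrs(lmrs, GROUPS6)
        assert len(ra) == 0  # consensus [1000,1500) has support 2 only

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            call_group_specific_lmrs({"RA_01": []}, {"RA_01": "RA"})


class TestJaccard:
    def test_identical_sets_have_unit_jaccard(self):
        lmrs = {"a": [lmr(0, 100)], "b": [lmr(0, 100)]}
        J, _ = jaccard_sample_clustering(lmrs)
        assert J.loc["a", "b"] == 1.0

    def test_disjoint_sets_have_zero_jaccard(self):
        lmrs = {"a": [lmr(0, 100)], "b": [lmr(200, 300)]}
        J, _ = jaccard_sample_clustering(lmrs)
        assert J.loc["a", "b"] == 0.0

    def test_partial_overlap_hand_computed(self):
        lmrs = {"a": [lmr(0, 100)], "b": [lmr(50, 150)]}
        J, _ = jaccard_sample_clustering(lmrs)
        assert J.loc["a", "b"] == pytest.approx(50 / 150)

    def test_empty_set_conventions(self):
        with pytest.warns(UserWarning, match="empty"):
            J, _ = jaccard_sample_clustering(
                {"a": [], "b": [], "c": [lmr(0, 10)]}
            )
        assert J.loc["a", "b"] == 1.0
        assert J.loc["a", "c"] == 0.0

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        lmrs = {
            f"s{i}": [lmr(int(a), int(a) + int(b))
                      for a, b in zip(rng.integers(0, 10000, 8), rng.integers(50, 400, 8))]
            for i in range(5)
        }
        J, _ = jaccard_sample_clustering(lmrs)
        assert np.allclose(J, J.T)
        assert np.allclose(np.diag(J), 1.0)
        assert ((J.to_numpy() >= 0) & (J.to_numpy() <= 1)).all()

    def test_group_specific_lmrs_separate_groups(self, segmented_cohort):
        samples, truth, segments = segmented_cohort
        lmrs = {
            sid: [x for x in segs if x.klass == "LMR"]
            for sid, segs in segments.items()
        }
        J, linkage = jaccard_sample_clustering(lmrs)
        cut = fcluster(linkage, 2, criterion="maxclust")
        by_cluster = {}
        for sid, c in zip(J.index, cut):
            by_cluster.setdefault(c, set()).add(sid[:2])
        assert sorted(map(tuple, by_cluster.values())) == [("OA",), ("RA",)]

    def test_newick_contains_all_labels(self):
        lmrs = {"a": [lmr(0, 100)], "b": [lmr(50, 150)], "c": [lmr(500, 600)]}
        J, linkage = jaccard_sample_clustering(lmrs)
        nwk = linkage_to_newick(linkage, list(J.index))
        assert nwk.endswith(";")
        for label in "abc":
            assert label in nwk


class TestProfiles:
    def _region_set(self, centers):
        regions = [
            GenomicInterval("chrS", c - 50, c + 50, name=f"r{i}")
            for i, c in enumerate(centers)
        ]
        import pandas as pd

        support = pd.DataFrame(
            {"n_ra_detected": 3, "n_oa_detected": 0},
            index=[r.name for r in regions],
        )
        return SpecificRegionSet("RA", regions, support)

    def test_two_planted_shapes_recovered_with_k2(self):
        # shape A: deep center dip; shape B: flat low profile
        n = 200
        betas = np.full(n, 0.9)
        betas[45:55] = 0.05  # dip at CpGs 45..54 (positions ~5000)
        betas[120:180] = 0.3  # broad flat-low block
        samples = [
            make_sample(betas, f"RA_{i:02d}", "RA", seed=i) for i in range(3)
        ] + [
            make_sample(betas, f"OA_{i:02d}", "OA", seed=10 + i) for i in range(3)
        ]
        centers = [int(samples[0].pos[49]), int(samples[0].pos[150])]
        rs = self._region_set(centers)
        _, labels = profile_and_cluster_lmrs(rs, samples, k=2, seed=0)
        assert labels[0] != labels[1]

    def test_k1_gives_single_cluster(self):
        samples = [make_sample(np.full(100, 0.5), f"RA_{i}", "RA") for i in range(2)]
        samples += [make_sample(np.full(100, 0.5), f"OA_{i}", "OA") for i in range(2)]
        rs = self._region_set([3000, 6000])
        _, labels = profile_and_cluster_lmrs(rs, samples, k=1, seed=0)
        assert set(labels) == {0}

    def test_duplicate_rows_with_k2_do_not_crash(self):
        samples = [make_sample(np.full(100, 0.5), f"RA_{i}", "RA") for i in range(2)]
        samples += [make_sample(np.full(100, 0.5), f"OA_{i}", "OA") for i in range(2)]
        rs = self._region_set([3000, 3000, 3000])
        _, labels = profile_and_cluster_lmrs(rs, samples, k=2, seed=0)
        assert len(labels) == 3

    def test_values_in_unit_interval(self):
        samples = [make_sample(np.linspace(0.05, 0.95, 150), f"RA_{i}", "RA")
                   for i in range(2)]
        samples += [make_sample(np.full(150, 0.8), f"OA_{i}", "OA") for i in range(2)]
        rs = self._region_set([4000])
        matrix, _ = profile_and_cluster_lmrs(rs, samples, k=1, seed=0)
        vals = matrix.values[~np.isnan(matrix.values)]
        assert ((vals >= 0) & (vals <= 1)).all()


def plus_gene(name="gplus"):
    # exons [1000,1200) [2000,2200) [3000,3400); introns at [1200,2000), [2200,3000)
    return GeneModel(
        GenomicInterval("chrS", 1000, 3400, name, "+"),
        (1000, 2000, 3000),
        (1200, 2200, 3400),
    )


def minus_gene(name="gminus"):
    return GeneModel(
        GenomicInterval("chrS", 1000, 3400, name, "-"),
        (1000, 2000, 3000),
        (1200, 2200, 3400),
    )


class TestAnnotation:
    def region(self, start, end):
        return GenomicInterval("chrS", start, end, name="r")

    def test_first_intron_plus_strand(self):
        rec = annotate_lmr_position([self.region(1500, 1600)], [plus_gene()])[0]
        assert rec.category == "intron"
        assert rec.intron_index == 1

    def test_same_intron_is_last_on_minus_strand(self):
        rec = annotate_lmr_position([self.region(1500, 1600)], [minus_gene()])[0]
        # genomically first intron is the 3'-most intron of a minus gene
        assert rec.category == "intron"
        assert rec.intron_index == 2

    def test_upstream_window_is_promoter(self):
        rec = annotate_lmr_position([self.region(400, 600)], [plus_gene()])[0]
        assert rec.category == "promoter"

    def test_minus_strand_promoter_is_downstream_in_genome_coords(self):
        rec = annotate_lmr_position([self.region(3500, 3700)], [minus_gene()])[0]
        assert rec.category == "promoter"

    def test_exon_midpoint(self):
        rec = annotate_lmr_position([self.region(2050, 2150)], [plus_gene()])[0]
        assert rec.category == "exon"

    def test_unknown_chromosome_is_intergenic_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            rec = annotate_lmr_position(
                [GenomicInterval("chrZ", 0, 100)], [plus_gene()]
            )[0]
        assert rec.category == "intergenic"

    def test_relative_position_strand_aware(self):
        plus = annotate_lmr_position([self.region(1200, 1280)], [plus_gene()])[0]
        minus = annotate_lmr_position([self.region(1200, 1280)], [minus_gene()])[0]
        assert plus.relative_position == pytest.approx(240 / 2400)
        assert minus.relative_position == pytest.approx((3399 - 1240) / 2400)


class TestEnhancerOverlap:
    def test_ratio_and_chisq_match_hand_computation(self):
        ra = [GenomicInterval("chrS", i * 1000, i * 1000 + 100) for i in range(10)]
        oa = [GenomicInterval("chrS", 100000 + i * 1000, 100000 + i * 1000 + 100)
              for i in range(10)]
        enhancers = [GenomicInterval("chrS", i * 1000, i * 1000 + 50) for i in range(8)]
        enhancers += [GenomicInterval("chrS", 100000 + i * 1000, 100000 + i * 1000 + 50)
                      for i in range(2)]
        res = enhancer_overlap_ratio(ra, oa, {"blood": enhancers})
        assert res.loc["blood", "ratio"] == pytest.approx(4.0)
        # independent 1-df Pearson chi-squared on [[8,2],[2,8]]
        table = np.array([[8, 2], [2, 8]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - exp) ** 2 / exp).sum()
        assert res.loc["blood", "chi2_p"] == pytest.approx(chi2.sf(stat, 1), rel=1e-12)

    def test_equal_fractions_ratio_one(self):
        ra = [GenomicInterval("chrS", 0, 100)]
        oa = [GenomicInterval("chrS", 0, 100)]
        enh = [GenomicInterval("chrS", 50, 60)]
        res = enhancer_overlap_ratio(ra, oa, {"x": enh})
        assert res.loc["x", "ratio"] == 1.0
        assert res.loc["x", "chi2_p"] == pytest.approx(1.0)

    def test_zero_oa_overlap_gives_infinite_ratio(self):
        ra = [GenomicInterval("chrS", 0, 100), GenomicInterval("chrS", 200, 300)]
        oa = [GenomicInterval("chrS", 5000, 5100)]
        enh = [GenomicInterval("chrS", 0, 50)]
        res = enhancer_overlap_ratio(ra, oa, {"x": enh})
        assert np.isinf(res.loc["x", "ratio"])
        assert 0 <= res.loc["x", "chi2_p"] <= 1
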
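import math

import numpy as np
import pytest
import scipy.stats

from methylscape.site_stats import (
    balanced_error_classification,
    bonferroni_threshold,
    dmc_dvc_overlap_significance,
    levene_w,
    qc_conversion_control,
    top_variable_cpg_clustering,
)
from methylscape.site_stats import test_dmc as dmc_test
from methylscape.site_stats import test_dvc as dvc_test
from methylscape.types import GenomicInterval

from conftest import make_sample


def cohort_from_matrix(betas, groups, cov=30, seed=None):
    """Samples from a (samples x sites) matrix of methylation levels."""
    out = []
    counts = {"RA": 0, "OA": 0}
    for i, (g, row) in enumerate(zip(groups, betas)):
        counts[g] += 1
        s = None if seed is None else seed + i
        out.append(make_sample(row, f"{g}_{counts[g]:02d}", g, cov=cov, seed=s))
    return out


class TestQc:
    region = GenomicInterval("chrS", 500, 3000)

    def test_highly_methylated_control_passes(self):
        s = make_sample(np.full(50, 0.95))
        assert qc_conversion_control(s, self.region) == "pass"

    def test_low_methylation_control_fails(self):
        # incomplete bisulfite conversion mimic: control region at beta 0.3
        s = make_sample(np.full(50, 0.3))
        assert qc_conversion_control(s, self.region) == "fail"

    def test_uncovered_region_is_indeterminate(self):
        s = make_sample(np.full(5, 0.9))
        far = GenomicInterval("chrS", 10**6, 10**6 + 100)
        assert qc_conversion_control(s, far) == "indeterminate"


class TestDmc:
    def test_complete_separation_is_strongly_significant_and_flagged(self):
        betas = np.vstack([np.ones((3, 5)), np.zeros((3, 5))])
        betas = np.hstack([betas, np.full((6, 5), 0.5)])  # null companions
        samples = cohort_from_matrix(betas, ["RA"] * 3 + ["OA"] * 3, cov=10)
        res = dmc_test(samples, min_cov=5)
        sep = res.iloc[:5]
        assert (sep["diff"] == 1.0).all()
        assert (sep["separation"]).all()
        # pooled-count binomial oracle: observing 30/30 vs 0/30 under a
        # common rate is astronomically unlikely; LRT p must be far below
        # any usual genome-wide threshold
        assert (sep["p_dmc"] < 1e-10).all()
        assert (sep["is_dmc"]).all()

    def test_identical_groups_have_zero_diff_and_no_calls(self):
        betas = np.tile(np.linspace(0.1, 0.9, 20), (6, 1))
        samples = cohort_from_matrix(betas, ["RA"] * 3 + ["OA"] * 3)
        res = dmc_test(samples)
        assert np.allclose(res["diff"], 0.0)
        assert not res["is_dmc"].any()

    def test_small_effect_fails_threshold_despite_tiny_p(self):
        betas = np.vstack([np.full((3, 10), 0.65), np.full((3, 10), 0.5)])
        samples = cohort_from_matrix(betas, ["RA"] * 3 + ["OA"] * 3, cov=100000)
        res = dmc_test(samples, min_cov=5)
        assert (res["p_dmc"] < 1e-12).all()
        assert not res["is_dmc"].any()  # |diff| = 0.15 <= 0.2

    def test_single_sample_group_rejected(self):
        betas = np.full((3, 10), 0.5)
        samples = cohort_from_matrix(betas, ["RA", "RA", "OA"])
        with pytest.raises(ValueError, match="2 samples"):
            dmc_test(samples)

    def test_printed_bonferroni_threshold_reproduced(self):
        thr = bonferroni_threshold(20_605_641)
        mantissa = math.floor(thr * 1e9 * 100) / 100  # 3-significant-digit truncation
        assert mantissa == 2.42


class TestDvc:
    def test_w_matches_hand_formula_on_toy_vectors(self):
        ra = np.array([0.5, 0.5, 0.5])
        oa = np.array([0.1, 0.5, 0.9])
        # deviations from group means: {0,0,0} and {0.4,0,0.4}
        z2 = np.array([0.4, 0.0, 0.4])
        grand = z2.sum() / 6
        num = 3 * grand**2 + 3 * (z2.mean() - grand) ** 2
        den = ((z2 - z2.mean()) ** 2).sum()
        expected = (6 - 2) / (2 - 1) * num / den
        assert levene_w([ra, oa]) == pytest.approx(expected, abs=1e-10)

    def test_vectorized_w_matches_scipy_levene(self):
        rng = np.random.default_rng(3)
        betas = rng.uniform(0.1, 0.9, size=(8, 50))
        samples = cohort_from_matrix(betas, ["RA"] * 4 + ["OA"] * 4, cov=1000)
        res = dvc_test(samples, min_cov=5)
        obs = np.stack([s.beta for s in samples])
        for i in range(50):
            w, p = scipy.stats.levene(obs[:4, i], obs[4:, i], center="mean")
            assert res["levene_w"].iloc[i] == pytest.approx(w, abs=1e-10)
            assert res["p_dvc"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_degenerate_identical_vectors_skipped(self):
        betas = np.full((6, 5), 0.5)
        samples = cohort_from_matrix(betas, ["RA"] * 3 + ["OA"] * 3)
        res = dvc_test(samples)
        assert res["skipped"].all()
        assert res["q_dvc"].isna().all()

    def test_null_calibration_near_nominal_level(self):
        # equal-variance groups, intermediate methylation, 20 vs 20
        rng = np.random.default_rng(5)
        n_cpg = 2000
        betas = np.clip(rng.normal(0.5, 0.1, size=(40, n_cpg)), 0.02, 0.98)
        samples = cohort_from_matrix(betas, ["RA"] * 20 + ["OA"] * 20, cov=30, seed=5)
        res = dvc_test(samples, min_cov=5)
        frac = (res["p_dvc"] < 0.05).mean()
        half_width = 1.96 * math.sqrt(0.05 * 0.95 / n_cpg)
        assert abs(frac - 0.05) <= half_width


def hypergeom_tail_exact(both, a, b, universe):
    """Exact enrichment tail with integer arithmetic (math.comb)."""
    total = math.comb(universe, a)
    acc = 0
    for k in range(both, min(a, b) + 1):
        acc += math.comb(b, k) * math.comb(universe - b, a - k)
    return acc / total


class TestOverlap:
    def test_fisher_p_equals_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            universe = int(rng.integers(20, 201))
            a = int(rng.integers(1, universe // 2))
            b = int(rng.integers(1, universe // 2))
            both = int(rng.integers(0, min(a, b) + 1))
            dmc = set(range(a))
            dvc = set(range(a - both, a - both + b))
            if len(dmc | dvc) > universe:
                continue
            res = dmc_dvc_overlap_significance(dmc, dvc, universe, n_perm=9)
            oracle = hypergeom_tail_exact(both, a, b, universe)
            assert res.fisher_p == pytest.approx(oracle, rel=1e-12)

    def test_expected_overlap_is_not_enriched(self):
        universe = 100
        dmc = set(range(10))
        dvc = set(range(9, 19))  # overlap 1 = expectation 10*10/100
        res = dmc_dvc_overlap_significance(dmc, dvc, universe, n_perm=999)
        assert res.fisher_p > 0.3

    def test_permutation_p_respects_add_one_floor(self):
        universe = 100
        dmc = set(range(10))
        res = dmc_dvc_overlap_significance(dmc, dmc, universe, n_perm=999, seed=0)
        assert res.permutation_p == pytest.approx(1 / 1000)

    def test_union_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            dmc_dvc_overlap_significance(set(range(10)), set(range(10, 20)), 15)


class TestBalancedError:
    labels = np.array(["RA"] * 6 + ["OA"] * 6)

    def test_perfectly_separating_features_give_zero_ber(self):
        beta = np.zeros((20, 12))
        beta[:, :6] = 0.9
        beta[:, 6:] = 0.1
        res = balanced_error_classification(
            beta, self.labels, {"dmc": np.arange(20)}, n_boot=10, n_perm=0
        )
        assert res["ber"]["dmc"] == 0.0
        assert np.all(res["ber_boot"]["dmc"] == 0.0)

    def test_random_labels_give_chance_level_ber(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(0.5, 0.1, size=(50, 12))
        bers = []
        for rep in range(30):
            labels = rng.permutation(self.labels)
            res = balanced_error_classification(
                beta, labels, {"f": np.arange(50)}, n_boot=1, n_perm=0, seed=rep
            )
            bers.append(res["ber"]["f"])
        assert abs(np.mean(bers) - 0.5) < 0.1

    def test_complementary_sets_combine_to_lower_ber(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0.5, 0.05, size=(100, 12))
        a, b = np.arange(50), np.arange(50, 100)
        beta[np.ix_(a, [0, 1, 2])] += 0.4  # informative for half the RA samples
        beta[np.ix_(b, [3, 4, 5])] += 0.4  # informative for the other half
        res = balanced_error_classification(
            beta, self.labels,
            {"a": a, "b": b, "both": np.arange(100)},
            n_boot=5, n_perm=99, seed=0,
        )
        assert res["ber"]["both"] <= min(res["ber"]["a"], res["ber"]["b"])

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            balanced_error_classification(
                np.zeros((5, 12)), self.labels, {"x": np.array([], dtype=int)}
            )


class TestTopVariable:
    def test_planted_high_sd_sites_selected_exactly(self):
        rng = np.random.default_rng(2)
        betas = np.full((6, 1000), 0.5) + rng.normal(0, 0.01, (6, 1000))
        planted = rng.choice(1000, 100, replace=False)
        betas[:, planted] += rng.normal(0, 0.4, (6, 100))
        betas = np.clip(betas, 0, 1)
        samples = cohort_from_matrix(betas, ["RA"] * 3 + ["OA"] * 3, cov=10000)
        selected, _ = top_variable_cpg_clustering(samples, n_top=100)
        got = set(selected["pos"])
        expected = {int(samples[0].pos[i]) for i in planted}
        assert got == expected

    def test_n_top_exceeding_sites_rejected(self):
        samples = cohort_from_matrix(np.full((4, 10), 0.5), ["RA"] * 2 + ["OA"] * 2)
        with pytest.raises(ValueError, match="exceeds"):
            top_variable_cpg_clustering(samples, n_top=11)

    def test_identical_samples_pair_at_zero_distance(self):
        betas = np.vstack([np.linspace(0.1, 0.9, 30)] * 4)
        betas[3] += 0.05
        samples = cohort_from_matrix(betas, ["RA"] * 2 + ["OA"] * 2, cov=1000)
        _, linkage = top_variable_cpg_clustering(samples, n_top=30)
        assert linkage[0, 2] == pytest.approx(0.0)
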
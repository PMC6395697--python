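import numpy as np
import pytest

from methylscape.segmentation import (
    ALPHA_MAX,
    CutoffSelection,
    CutoffSelectionError,
    call_umr_lmr,
    classify_pmd_sharing,
    compute_alpha_track,
    detect_pmds,
    fit_symmetric_beta_alpha,
    select_fdr_cutoff,
    smoothed_beta,
)
from methylscape.synthetic import CohortConfig, base_level_f1, simulate_methylome_cohort
from methylscape.types import GenomicInterval, Segment

from conftest import make_sample


def grid_search_alpha(betas, grid=None):
    """Independent ML oracle: exhaustive search over a fine alpha grid."""
    from scipy.special import gammaln

    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-3), np.log(ALPHA_MAX), 20001))
    b = np.asarray(betas)
    s = np.sum(np.log(b) + np.log1p(-b))
    ll = len(b) * (gammaln(2 * grid) - 2 * gammaln(grid)) + (grid - 1) * s
    return grid[np.argmax(ll)]


class TestAlphaEstimation:
    @pytest.mark.parametrize(
        "betas",
        [
            np.tile([0.02, 0.98, 0.03, 0.97], 26)[:101],  # polarized
            np.random.default_rng(0).beta(1.5, 1.5, 101),  # dispersed
            np.random.default_rng(1).beta(20, 2, 101),  # high plateau
            np.random.default_rng(2).uniform(0.05, 0.95, 101),
        ],
    )
    def test_ml_fit_matches_grid_search_oracle(self, betas):
        alpha = fit_symmetric_beta_alpha(betas)
        oracle = grid_search_alpha(betas)
        assert abs(alpha - oracle) <= 0.01

    def test_polarized_window_gives_alpha_below_one(self):
        betas = np.tile([0.02, 0.98], 51)[:101]
        assert fit_symmetric_beta_alpha(betas) < 1.0

    def test_uniform_half_window_gives_alpha_above_one(self):
        assert fit_symmetric_beta_alpha(np.full(101, 0.5)) > 1.0

    def test_track_window_shorter_than_sample_is_empty_with_warning(self):
        s = make_sample(np.full(5, 0.5))
        with pytest.warns(UserWarning, match="fewer CpGs"):
            track = compute_alpha_track(s, window_cpgs=101)
        assert len(track) == 0

    def test_even_window_rejected(self):
        s = make_sample(np.full(200, 0.5))
        with pytest.raises(ValueError, match="odd"):
            compute_alpha_track(s, window_cpgs=100)

    def test_track_alphas_positive_and_ordered(self):
        rng = np.random.default_rng(3)
        s = make_sample(rng.beta(2, 2, 500), seed=3)
        track = compute_alpha_track(s, window_cpgs=101)
        assert (track.alpha > 0).all()
        assert (np.diff(track.center_index) == 1).all()


def polarized_betas(rng, n):
    lows = rng.random(n) < 0.2
    b = rng.beta(20, 2, n)
    b[lows] = rng.beta(2, 20, int(lows.sum()))
    return b


class TestPmdDetection:
    def test_planted_pmd_recovered_with_high_jaccard(self):
        rng = np.random.default_rng(10)
        n = 12000
        betas = polarized_betas(rng, n)
        betas[5000:7000] = rng.beta(1.5, 1.5, 2000)  # planted PMD
        s = make_sample(betas, cov=22, seed=10)
        track = compute_alpha_track(s, 101)
        pmds = detect_pmds(track, s, window_cpgs=101)
        assert len(pmds) == 1
        truth = GenomicInterval("chrS", int(s.pos[5000]), int(s.pos[6999]) + 1)
        inter = pmds[0].interval.overlap_bp(truth)
        union = pmds[0].interval.length + truth.length - inter
        assert inter / union >= 0.9

    def test_no_planted_pmd_gives_empty_list(self):
        rng = np.random.default_rng(11)
        s = make_sample(polarized_betas(rng, 5000), cov=22, seed=11)
        track = compute_alpha_track(s, 101)
        assert detect_pmds(track, s, window_cpgs=101) == []

    def test_fully_dispersed_genome_is_one_pmd(self):
        rng = np.random.default_rng(12)
        s = make_sample(rng.beta(1.5, 1.5, 3000), cov=22, seed=12)
        track = compute_alpha_track(s, 101)
        pmds = detect_pmds(track, s, window_cpgs=101)
        assert len(pmds) == 1
        # spans the whole tracked region (window centers)
        assert pmds[0].interval.start == int(s.pos[50])
        assert pmds[0].interval.end == int(s.pos[2949]) + 1


def seg(start, end):
    return Segment(GenomicInterval("chrS", start, end), "PMD", 200, 0.5)


class TestPmdSharing:
    def test_cross_group_overlap_makes_both_shared(self):
        pmds = {"RA_01": [seg(0, 1000)], "OA_01": [seg(500, 2000)]}
        groups = {"RA_01": "RA", "OA_01": "OA"}
        labels = classify_pmd_sharing(pmds, groups)
        assert labels["RA_01"][0][1] == "shared"
        assert labels["OA_01"][0][1] == "shared"

    def test_single_sample_pmd_is_specific(self):
        pmds = {"RA_01": [seg(0, 1000)], "RA_02": [], "OA_01": []}
        groups = {"RA_01": "RA", "RA_02": "RA", "OA_01": "OA"}
        assert classify_pmd_sharing(pmds, groups)["RA_01"][0][1] == "specific"

    def test_empty_input_gives_empty_labeling(self):
        assert classify_pmd_sharing({}, {}) == {}

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValueError, match="group"):
            classify_pmd_sharing({"X": [seg(0, 10)]}, {"X": "ctrl"})


class TestCutoffSelection:
    def _structured_sample(self, seed=20, n=8000):
        rng = np.random.default_rng(seed)
        betas = rng.beta(20, 2, n)
        for start in range(200, n - 20, 250):
            betas[start : start + 12] = rng.beta(5, 45, 12)  # planted LMRs
        return make_sample(betas, cov=22, seed=seed)

    def test_structured_input_selects_cutoff_within_grid(self):
        s = self._structured_sample()
        sel = select_fdr_cutoff(s, [], seed=0)
        assert 0.30 <= sel.chosen_m <= 0.70
        assert sel.fdr_table.loc[sel.chosen_m, sel.chosen_n] <= 0.05

    def test_structureless_input_fails_selection(self):
        rng = np.random.default_rng(21)
        s = self._structured_sample()
        # destroy all spatial structure by permuting the methylation values
        perm = rng.permutation(len(s))
        shuffled = make_sample(np.zeros(len(s)))
        shuffled.cov = s.cov[perm]
        shuffled.meth = s.meth[perm]
        with pytest.raises(CutoffSelectionError):
            select_fdr_cutoff(shuffled, [], seed=0)

    def test_same_seed_identical_selection(self):
        s = self._structured_sample()
        a = select_fdr_cutoff(s, [], seed=7)
        b = select_fdr_cutoff(s, [], seed=7)
        assert a.chosen_m == b.chosen_m and a.chosen_n == b.chosen_n
        assert a.fdr_table.equals(b.fdr_table)


def fixed_cutoff(m=0.5, n=4):
    import pandas as pd

    grid_m = np.array([m])
    grid_n = np.array([n])
    return CutoffSelection(
        grid_m, grid_n, pd.DataFrame([[0.0]], index=grid_m, columns=grid_n),
        chosen_m=m, chosen_n=n, fdr_bound=0.05,
    )


class TestUmrLmrCalling:
    def _sample_with_run(self, run_len, low=0.02):
        betas = np.full(run_len + 200, 0.9)
        betas[100 : 100 + run_len] = low
        return make_sample(betas)

    def test_thirty_cpg_run_is_umr(self):
        s = self._sample_with_run(30)
        segs = call_umr_lmr(s, [], fixed_cutoff())
        assert [x.klass for x in segs] == ["UMR"]
        assert segs[0].n_cpg == 30

    def test_twentynine_cpg_run_is_lmr(self):
        s = self._sample_with_run(29, low=0.2)
        segs = call_umr_lmr(s, [], fixed_cutoff())
        assert [x.klass for x in segs] == ["LMR"]
        assert segs[0].n_cpg == 29

    def test_no_cpg_below_cutoff_gives_empty(self):
        s = make_sample(np.full(300, 0.9))
        assert call_umr_lmr(s, [], fixed_cutoff()) == []

    def test_runs_do_not_cross_pmd_mask(self):
        s = self._sample_with_run(40)
        pmd = [Segment(GenomicInterval("chrS", int(s.pos[110]), int(s.pos[119]) + 1),
                       "PMD", 10, 0.5)]
        segs = call_umr_lmr(s, pmd, fixed_cutoff())
        # the PMD splits the 40-CpG run into two sub-30 runs -> two LMRs
        assert [x.klass for x in segs] == ["LMR", "LMR"]
        for x in segs:
            assert x.interval.overlap_bp(pmd[0].interval) == 0

    def test_segment_boundaries_are_run_endpoints(self):
        s = self._sample_with_run(29, low=0.2)
        segs = call_umr_lmr(s, [], fixed_cutoff())
        # edge CpGs average with the high flank, so the smoothed run is
        # exactly the planted 29 CpGs at indices 100..128
        assert segs[0].interval.start == int(s.pos[100])
        assert segs[0].interval.end == int(s.pos[128]) + 1


class TestSegmentInvariants:
    def test_segments_sorted_nonoverlapping_and_outside_pmds(self, segmented_cohort):
        _, _, segments = segmented_cohort
        for sid, segs in segments.items():
            pmds = [x for x in segs if x.klass == "PMD"]
            hypo = [x for x in segs if x.klass != "PMD"]
            for x in hypo:
                for p in pmds:
                    assert x.interval.overlap_bp(p.interval) == 0
            ordered = sorted(hypo, key=lambda x: x.interval.start)
            for a, b in zip(ordered, ordered[1:]):
                assert a.interval.end <= b.interval.start
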
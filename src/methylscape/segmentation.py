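"""Methylome segmentation into PMDs, UMRs and LMRs.

The segmentation proceeds in two passes per sample:

1. **PMD detection.**  A sliding window of ``window_cpgs`` consecutive CpGs
   is summarized by the maximum-likelihood shape ``alpha`` of a symmetric
   Beta(alpha, alpha) distribution fitted to the window's
   posterior-smoothed beta values ``(meth + 0.5) / (cov + 1)``.
   ``alpha < 1`` marks a polarized (bimodal, well-ordered) landscape;
   ``alpha >= 1`` marks the dispersed intermediate methylation typical of
   partially methylated domains.  A two-state Gaussian HMM on ``log alpha``
   is trained by EM (deterministic median-split initialization) and decoded
   by posterior probability; the state with the larger mean ``log alpha``
   is the PMD state.  A state only qualifies as PMD if its mean
   ``log alpha`` is positive, which makes the caller return nothing on a
   fully polarized genome and everything on a fully dispersed one.

2. **UMR/LMR calling.**  Outside PMDs, betas are smoothed over three
   consecutive CpGs and maximal runs of at least ``n`` CpGs below the
   methylation cutoff ``m`` become hypomethylated segments.  The (m, n)
   pair is selected against a genome-wide permutation of the beta values:
   FDR(m, n) = calls(permuted) / calls(observed), and the largest m with
   FDR below the bound at the fixed n is chosen.  Segments with >= 30 CpGs
   are classified UMR, smaller ones LMR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.special import digamma

from .types import GenomicInterval, MethylomeSample, MethylscapeError, Segment

LN2 = float(np.log(2.0))
ALPHA_MAX = 100.0
ALPHA_MIN = 1e-3


class ConvergenceError(MethylscapeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, history):
        super().__init__(message)
        self.history = list(history)


class CutoffSelectionError(MethylscapeError):
    """No (m, n) cutoff satisfies the FDR bound."""


@dataclass
class AlphaTrack:
    """Per-window polarization estimates along the genome."""

    chrom: np.ndarray  # chromosome per window center
    center_index: np.ndarray  # CpG index of the window center
    alpha: np.ndarray  # ML symmetric-Beta shape, > 0

    def __len__(self) -> int:
        return len(self.alpha)


def smoothed_beta(sample: MethylomeSample) -> np.ndarray:
    """Posterior-smoothed methylation level (pseudocount 0.5 / 1)."""
    return (sample.meth + 0.5) / (sample.cov + 1.0)


def _alpha_from_target(t: np.ndarray) -> np.ndarray:
    """Solve digamma(2a) - digamma(a) = t for a (vectorized bisection).

    The left side decreases monotonically from +inf (a -> 0) to log 2
    (a -> inf), so a unique root exists for every t > log 2.  Targets at
    or below log 2 (all betas exactly 0.5) saturate at ``ALPHA_MAX``.
    """
    t = np.asarray(t, dtype=float)
    lo = np.full_like(t, np.log(ALPHA_MIN))
    hi = np.full_like(t, np.log(ALPHA_MAX))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        a = np.exp(mid)
        f = digamma(2 * a) - digamma(a)
        go_right = f > t
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    alpha = np.exp(0.5 * (lo + hi))
    return np.where(t <= LN2 + 1e-12, ALPHA_MAX, alpha)


def fit_symmetric_beta_alpha(betas: np.ndarray) -> float:
    """ML estimate of alpha for one window of beta values in (0, 1)."""
    b = np.asarray(betas, dtype=float)
    s = np.mean(np.log(b) + np.log1p(-b))
    return float(_alpha_from_target(np.array([-s / 2.0]))[0])


def compute_alpha_track(sample: MethylomeSample, window_cpgs: int = 101) -> AlphaTrack:
    """Fit alpha in every sliding window of ``window_cpgs`` consecutive CpGs."""
    if window_cpgs < 3 or window_cpgs % 2 == 0:
        raise ValueError("window_cpgs must be odd and >= 3")
    if len(sample) == 0:
        raise ValueError("sample has no CpGs")
    beta = smoothed_beta(sample)
    logterm = np.log(beta) + np.log1p(-beta)
    half = window_cpgs // 2
    chroms_out, centers_out, alphas_out = [], [], []
    # windows never span a chromosome boundary
    for chrom, start, stop in _chrom_blocks(sample.chrom):
        n = stop - start
        if n < window_cpgs:
            continue
        win = np.lib.stride_tricks.sliding_window_view(
            logterm[start:stop], window_cpgs
        )
        t = -win.mean(axis=1) / 2.0
        alpha = _alpha_from_target(t)
        centers = np.arange(start + half, stop - half)
        chroms_out.append(np.full(len(centers), chrom, dtype=object))
        centers_out.append(centers)
        alphas_out.append(alpha)
    if not centers_out:
        warnings.warn(
            f"sample {sample.sample_id}: fewer CpGs than window size; empty track",
            stacklevel=2,
        )
        return AlphaTrack(
            np.array([], dtype=object), np.array([], dtype=int), np.array([])
        )
    return AlphaTrack(
        np.concatenate(chroms_out),
        np.concatenate(centers_out),
        np.concatenate(alphas_out),
    )


def _chrom_blocks(chrom_arr: np.ndarray):
    """Yield (chrom, start, stop) index blocks of consecutive equal chroms."""
    n = len(chrom_arr)
    if n == 0:
        return
    start = 0
    for i in range(1, n + 1):
        if i == n or chrom_arr[i] != chrom_arr[start]:
            yield chrom_arr[start], start, i
            start = i


def detect_pmds(
    track: AlphaTrack,
    sample: MethylomeSample,
    min_pmd_cpgs: int | None = None,
    window_cpgs: int = 101,
    max_iter: int = 100,
    tol: float = 1e-6,
    log_alpha_min: float = 0.0,
) -> list[Segment]:
    """Decode PMDs from the alpha track with a two-state Gaussian HMM.

    Emissions are Gaussian on ``log alpha``; EM is initialized by a median
    split of ``log alpha`` (no random initialization).  A decoded state is
    accepted as PMD only if its mean ``log alpha`` exceeds
    ``log_alpha_min`` (alpha >= 1, dispersed).
    """
    if len(track) == 0:
        raise ValueError("empty alpha track")
    if min_pmd_cpgs is None:
        min_pmd_cpgs = window_cpgs
    x = np.log(track.alpha)[:, None]
    # deterministic init anchored at the polarized/dispersed boundary
    # (alpha = 1): the PMD state starts at the mean of dispersed windows
    lo_vals, hi_vals = x[x <= log_alpha_min], x[x > log_alpha_min]
    if len(hi_vals) == 0 or len(lo_vals) == 0:  # one-sided track
        med = np.median(x)
        lo_vals, hi_vals = x[x <= med], x[x > med]
        if len(hi_vals) == 0:
            hi_vals = lo_vals
    means = np.array([[lo_vals.mean()], [hi_vals.mean()]])
    var = max(float(np.var(x)), 1e-4)

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="stmc",
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = means
    model.covars_ = np.full((2, 1), var)
    lengths = [stop - start for _, start, stop in _chrom_blocks(track.chrom)]
    import logging

    hmm_log = logging.getLogger("hmmlearn.base")
    old_level = hmm_log.level
    hmm_log.setLevel(logging.ERROR)  # monitor logs tiny negative deltas
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, lengths)
    finally:
        hmm_log.setLevel(old_level)
    if not model.monitor_.converged:
        raise ConvergenceError(
            f"PMD HMM did not converge within {max_iter} EM iterations",
            model.monitor_.history,
        )

    mu = model.means_.ravel()
    qualifying = [k for k in range(2) if mu[k] > log_alpha_min]
    if not qualifying:
        return []
    if len(qualifying) == 2:
        is_pmd = np.ones(len(track), dtype=bool)
    else:
        post = model.predict_proba(x, lengths)
        is_pmd = post[:, qualifying[0]] > 0.5

    return _windows_to_segments(
        track, sample, is_pmd, klass="PMD", min_cpgs=min_pmd_cpgs
    )


def _windows_to_segments(
    track: AlphaTrack,
    sample: MethylomeSample,
    flags: np.ndarray,
    klass: str,
    min_cpgs: int,
) -> list[Segment]:
    """Merge flagged consecutive window centers into segments."""
    beta = sample.beta
    segments: list[Segment] = []
    i, n = 0, len(track)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and flags[j + 1]
            and track.chrom[j + 1] == track.chrom[i]
            and track.center_index[j + 1] == track.center_index[j] + 1
        ):
            j += 1
        a, b = int(track.center_index[i]), int(track.center_index[j])
        n_cpg = b - a + 1
        if n_cpg >= min_cpgs:
            segments.append(
                Segment(
                    GenomicInterval(
                        str(track.chrom[i]),
                        int(sample.pos[a]),
                        int(sample.pos[b]) + 1,
                    ),
                    klass,
                    n_cpg,
                    float(np.nanmean(beta[a : b + 1])),
                )
            )
        i = j + 1
    return segments


def classify_pmd_sharing(
    pmds_by_sample: dict[str, list[Segment]], groups: dict[str, str]
) -> dict[str, list[tuple[Segment, str]]]:
    """Label each sample's PMDs as shared or specific.

    A PMD is *shared* when it colocalizes (>= 1 bp) with a PMD of any
    sample of the other group; it is *specific* when it is found in
    exactly one sample overall and overlaps no other-group PMD.  PMDs
    found in several same-group samples but no other-group sample get no
    label (returned as "unclassified").
    """
    for sid in pmds_by_sample:
        if sid not in groups:
            raise ValueError(f"unknown group for sample {sid!r}")
        if groups[sid] not in ("RA", "OA"):
            raise ValueError(f"unknown group label {groups[sid]!r}")
    out: dict[str, list[tuple[Segment, str]]] = {}
    for sid, pmds in pmds_by_sample.items():
        other = [
            seg
            for osid, osegs in pmds_by_sample.items()
            if groups[osid] != groups[sid]
            for seg in osegs
        ]
        same_other_samples = [
            osegs
            for osid, osegs in pmds_by_sample.items()
            if osid != sid
        ]
        labeled = []
        for seg in pmds:
            if any(seg.interval.overlaps(o.interval) for o in other):
                labeled.append((seg, "shared"))
            elif not any(
                seg.interval.overlaps(o.interval)
                for osegs in same_other_samples
                for o in osegs
            ):
                labeled.append((seg, "specific"))
            else:
                labeled.append((seg, "unclassified"))
        out[sid] = labeled
    return out


@dataclass
class CutoffSelection:
    """Grid-search FDR table and the chosen (m, n) cutoff."""

    m_grid: np.ndarray
    n_grid: np.ndarray
    fdr_table: pd.DataFrame  # index = m, columns = n
    chosen_m: float
    chosen_n: int
    fdr_bound: float


def _pmd_cpg_mask(sample: MethylomeSample, pmds: list[Segment]) -> np.ndarray:
    mask = np.zeros(len(sample), dtype=bool)
    for seg in pmds:
        iv = seg.interval
        in_iv = (
            (sample.chrom == iv.chrom)
            & (sample.pos >= iv.start)
            & (sample.pos < iv.end)
        )
        mask |= in_iv
    return mask


def _smooth3(beta: np.ndarray, chrom: np.ndarray) -> np.ndarray:
    """Centered moving mean over 3 CpGs, within chromosomes."""
    out = np.empty_like(beta, dtype=float)
    for _, start, stop in _chrom_blocks(chrom):
        seg = pd.Series(beta[start:stop])
        out[start:stop] = seg.rolling(3, center=True, min_periods=1).mean().to_numpy()
    return out


def _run_lengths(below: np.ndarray, chrom: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, never crossing chromosome boundaries.

    Returns (start_index, length) pairs.
    """
    runs = []
    for _, cstart, cstop in _chrom_blocks(chrom):
        i = cstart
        while i < cstop:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < cstop and below[j + 1]:
                j += 1
            runs.append((i, j - i + 1))
            i = j + 1
    return runs


def _count_calls(
    smoothed: np.ndarray,
    chrom: np.ndarray,
    masked: np.ndarray,
    m_grid: np.ndarray,
    n_grid: np.ndarray,
) -> np.ndarray:
    """Call counts per (m, n) grid point; masked CpGs break runs."""
    counts = np.zeros((len(m_grid), len(n_grid)), dtype=int)
    for mi, m in enumerate(m_grid):
        below = (smoothed < m) & ~masked
        lengths = np.array([ln for _, ln in _run_lengths(below, chrom)], dtype=int)
        for ni, n in enumerate(n_grid):
            counts[mi, ni] = int((lengths >= n).sum()) if len(lengths) else 0
    return counts


def select_fdr_cutoff(
    sample: MethylomeSample,
    pmds: list[Segment],
    m_grid: np.ndarray | None = None,
    n_grid: np.ndarray | None = None,
    fdr_bound: float = 0.05,
    fixed_n: int = 5,
    seed: int = 0,
    n_permutations: int = 5,
) -> CutoffSelection:
    """Choose the hypomethylation cutoff by permutation FDR.

    For each (m, n), hypomethylated-region calls in the observed methylome
    are compared with the mean call count over ``n_permutations``
    methylomes whose beta values were permuted genome-wide (fixed seed);
    FDR = permuted / observed, capped at 1.  Averaging several
    permutations keeps the estimate stable when null call counts are
    small.  The chosen m is the largest cutoff with FDR <= bound at the
    fixed n.
    """
    if m_grid is None:
        m_grid = np.round(np.arange(0.30, 0.7001, 0.05), 2)
    if n_grid is None:
        n_grid = np.arange(4, 11)
    if fixed_n not in n_grid:
        raise ValueError("fixed_n must be on the n grid")
    masked = _pmd_cpg_mask(sample, pmds)
    beta = sample.beta.copy()

    rng = np.random.default_rng(seed)
    free = np.flatnonzero(~masked)
    obs_smooth = _smooth3(beta, sample.chrom)
    obs = _count_calls(obs_smooth, sample.chrom, masked, m_grid, n_grid)
    perm_total = np.zeros_like(obs, dtype=float)
    for _ in range(n_permutations):
        perm_beta = beta.copy()
        perm_beta[free] = beta[free][rng.permutation(len(free))]
        perm_smooth = _smooth3(perm_beta, sample.chrom)
        perm_total += _count_calls(perm_smooth, sample.chrom, masked, m_grid, n_grid)
    # add-one smoothing over the pooled permutations (a lone chance call
    # must not yield FDR = 0)
    perm = (perm_total + 1) / n_permutations

    if obs.sum() == 0:
        raise CutoffSelectionError("no callable regions at any grid point")
    fdr = np.where(obs > 0, np.minimum(perm / np.maximum(obs, 1), 1.0), 1.0)
    table = pd.DataFrame(fdr, index=m_grid, columns=n_grid)

    ni = int(np.where(n_grid == fixed_n)[0][0])
    ok = [m for mi, m in enumerate(m_grid) if fdr[mi, ni] <= fdr_bound and obs[mi, ni] > 0]
    if not ok:
        raise CutoffSelectionError(
            f"no methylation cutoff reaches FDR <= {fdr_bound} at n = {fixed_n}"
        )
    return CutoffSelection(
        m_grid, n_grid, table, chosen_m=float(max(ok)), chosen_n=int(fixed_n),
        fdr_bound=fdr_bound,
    )


def call_umr_lmr(
    sample: MethylomeSample,
    pmds: list[Segment],
    cutoff: CutoffSelection,
) -> list[Segment]:
    """Call UMRs/LMRs outside PMDs at the selected cutoff.

    Betas are smoothed over 3 consecutive CpGs; maximal runs of at least
    ``chosen_n`` CpGs with smoothed beta below ``chosen_m`` become
    segments spanning the first to last CpG of the run (half-open end =
    last position + 1).  Runs with >= 30 CpGs are UMRs, smaller ones
    LMRs.
    """
    masked = _pmd_cpg_mask(sample, pmds)
    beta = sample.beta
    smooth = _smooth3(beta, sample.chrom)
    below = (smooth < cutoff.chosen_m) & ~masked
    segments: list[Segment] = []
    for start, length in _run_lengths(below, sample.chrom):
        if length < cutoff.chosen_n:
            continue
        stop = start + length - 1
        from .types import UMR_MIN_CPGS

        klass = "UMR" if length >= UMR_MIN_CPGS else "LMR"
        segments.append(
            Segment(
                GenomicInterval(
                    str(sample.chrom[start]),
                    int(sample.pos[start]),
                    int(sample.pos[stop]) + 1,
                ),
                klass,
                length,
                float(np.nanmean(beta[start : stop + 1])),
            )
        )
    return segments


def segment_sample(
    sample: MethylomeSample,
    window_cpgs: int = 101,
    fdr_bound: float = 0.05,
    fixed_n: int = 5,
    seed: int = 0,
) -> tuple[list[Segment], CutoffSelection]:
    """Full per-sample segmentation: PMDs, then UMRs/LMRs outside them."""
    track = compute_alpha_track(sample, window_cpgs)
    pmds = detect_pmds(track, sample, window_cpgs=window_cpgs) if len(track) else []
    cutoff = select_fdr_cutoff(
        sample, pmds, fdr_bound=fdr_bound, fixed_n=fixed_n, seed=seed
    )
    hypo = call_umr_lmr(sample, pmds, cutoff)
    return pmds + hypo, cutoff
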
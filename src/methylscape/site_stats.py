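"""Single-CpG statistics: QC, DMC/DVC tests, overlap and classification.

DMCs (differentially methylated CpGs) are called by per-CpG binomial
logistic regression of (methylated, unmethylated) counts on the group
indicator; with a single binary covariate the MLE is the pooled per-group
proportion, so the likelihood-ratio statistic has a closed form that is
evaluated vectorized across all sites.  A CpG is a DMC when the
unweighted group mean-beta difference exceeds 0.2 in absolute value and
the LRT p value clears the Bonferroni threshold 0.05 / N_tested.

DVCs (differentially variable CpGs) are called by Levene's test (classic
group-mean centering; Brown-Forsythe median centering available) with
Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import xlogy
from scipy.stats import chi2, f as f_dist, fisher_exact
from statsmodels.stats.multitest import multipletests

from .types import GenomicInterval, MethylomeSample


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling FWER at ``alpha``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def qc_conversion_control(
    sample: MethylomeSample,
    control_region: GenomicInterval,
    min_mean_beta: float = 0.8,
) -> str:
    """Bisulfite-conversion QC on an internal control region.

    The control region (e.g. the constitutively methylated gene-body
    marker used for WGBS QC) must show high methylation; a low mean beta
    indicates incomplete conversion and flags the sample for exclusion.
    Returns "pass", "fail", or "indeterminate" (no covered CpG).
    """
    on = (
        (sample.chrom == control_region.chrom)
        & (sample.pos >= control_region.start)
        & (sample.pos < control_region.end)
        & (sample.cov > 0)
    )
    if not on.any():
        return "indeterminate"
    return "pass" if float(np.nanmean(sample.beta[on])) >= min_mean_beta else "fail"


def align_cohort(
    samples: list[MethylomeSample], min_cov: int = 1
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Common-site matrices across a cohort.

    Returns (site table with chrom/pos, meth matrix, cov matrix), both
    matrices samples x sites, restricted to sites present with coverage
    >= ``min_cov`` in every sample.
    """
    if not samples:
        raise ValueError("empty cohort")
    keys = [pd.MultiIndex.from_arrays([s.chrom, s.pos]) for s in samples]
    common = keys[0]
    for k in keys[1:]:
        common = common.intersection(k)
    common = common.sortlevel([0, 1])[0]
    meth = np.empty((len(samples), len(common)), dtype=np.int64)
    cov = np.empty_like(meth)
    for i, (s, k) in enumerate(zip(samples, keys)):
        loc = k.get_indexer(common)
        meth[i] = s.meth[loc]
        cov[i] = s.cov[loc]
    ok = (cov >= min_cov).all(axis=0)
    sites = pd.DataFrame(
        {"chrom": common.get_level_values(0)[ok], "pos": common.get_level_values(1)[ok]}
    )
    return sites, meth[:, ok], cov[:, ok]


def _group_masks(samples: list[MethylomeSample]) -> tuple[np.ndarray, np.ndarray]:
    ra = np.array([s.group == "RA" for s in samples])
    return ra, ~ra


def test_dmc(
    samples: list[MethylomeSample],
    min_cov: int = 5,
    diff_threshold: float = 0.2,
    alpha: float = 0.05,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Differential methylation test at every commonly covered CpG.

    Closed-form binomial-logistic likelihood-ratio test of group effect;
    ``diff`` is the difference of unweighted per-sample mean betas
    (RA - OA).  The Bonferroni universe defaults to the number of CpGs
    actually tested.  Complete separation (pooled group proportion 0 vs
    1) is flagged; its deviance is finite by construction (xlogy).
    """
    ra, oa = _group_masks(samples)
    if ra.sum() < 2 or oa.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    sites, meth, cov = align_cohort(samples, min_cov=min_cov)
    n_tested = len(sites)
    if n_tested == 0:
        raise ValueError("no CpG passes the coverage filter in every sample")

    def pooled_ll(m: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        M, C = m.sum(axis=0), c.sum(axis=0)
        p = np.where(C > 0, M / np.maximum(C, 1), 0.0)
        ll = xlogy(M, p) + xlogy(C - M, 1.0 - p)
        return p, ll

    p_ra, ll_ra = pooled_ll(meth[ra], cov[ra])
    p_oa, ll_oa = pooled_ll(meth[oa], cov[oa])
    _, ll_null = pooled_ll(meth, cov)
    lrt = np.maximum(2.0 * (ll_ra + ll_oa - ll_null), 0.0)
    p_val = chi2.sf(lrt, df=1)

    beta = meth / cov
    diff = beta[ra].mean(axis=0) - beta[oa].mean(axis=0)
    universe = universe_size if universe_size is not None else n_tested
    thr = bonferroni_threshold(universe, alpha)
    is_dmc = (np.abs(diff) > diff_threshold) & (p_val < thr)
    separation = ((p_ra == 0) & (p_oa == 1)) | ((p_ra == 1) & (p_oa == 0))

    out = sites.copy()
    out["mean_beta_ra"] = beta[ra].mean(axis=0)
    out["mean_beta_oa"] = beta[oa].mean(axis=0)
    out["diff"] = diff
    out["lrt"] = lrt
    out["p_dmc"] = p_val
    out["is_dmc"] = is_dmc
    out["dmc_direction"] = np.where(
        ~is_dmc, "", np.where(diff > 0, "hyper", "hypo")
    )
    out["separation"] = separation
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tested"] = n_tested
    return out


def levene_w(values_by_group: list[np.ndarray], center: str = "mean") -> float:
    """Levene's W for one site (reference implementation, unvectorized)."""
    zs = []
    for v in values_by_group:
        c = np.mean(v) if center == "mean" else np.median(v)
        zs.append(np.abs(v - c))
    k = len(zs)
    n = sum(len(z) for z in zs)
    grand = np.concatenate(zs).mean()
    num = sum(len(z) * (z.mean() - grand) ** 2 for z in zs)
    den = sum(((z - z.mean()) ** 2).sum() for z in zs)
    if den == 0:
        return np.nan
    return (n - k) / (k - 1) * num / den


def test_dvc(
    samples: list[MethylomeSample],
    min_cov: int = 5,
    fdr: float = 0.05,
    center: str = "mean",
) -> pd.DataFrame:
    """Differential variability test (Levene) at every covered CpG.

    Sites where all within-group deviations vanish are skipped (reported
    with NaN statistics and ``skipped=True``); Benjamini-Hochberg q
    values are computed across the tested sites only.
    """
    ra, oa = _group_masks(samples)
    if ra.sum() < 2 or oa.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    sites, meth, cov = align_cohort(samples, min_cov=min_cov)
    beta = meth / cov

    def group_z(b: np.ndarray) -> np.ndarray:
        if center == "mean":
            c = b.mean(axis=0)
        else:
            c = np.median(b, axis=0)
        return np.abs(b - c)

    z_ra, z_oa = group_z(beta[ra]), group_z(beta[oa])
    n1, n2 = int(ra.sum()), int(oa.sum())
    n = n1 + n2
    zbar1, zbar2 = z_ra.mean(axis=0), z_oa.mean(axis=0)
    grand = (n1 * zbar1 + n2 * zbar2) / n
    num = n1 * (zbar1 - grand) ** 2 + n2 * (zbar2 - grand) ** 2
    den = ((z_ra - zbar1) ** 2).sum(axis=0) + ((z_oa - zbar2) ** 2).sum(axis=0)
    skipped = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(skipped, np.nan, (n - 2) / 1.0 * num / np.where(skipped, 1, den))
    p = np.where(skipped, np.nan, f_dist.sf(W, 1, n - 2))

    q = np.full_like(p, np.nan)
    tested = ~skipped
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    var_ra = beta[ra].var(axis=0, ddof=1)
    var_oa = beta[oa].var(axis=0, ddof=1)
    out = sites.copy()
    out["var_ra"] = var_ra
    out["var_oa"] = var_oa
    out["levene_w"] = W
    out["p_dvc"] = p
    out["q_dvc"] = q
    out["skipped"] = skipped
    out["is_dvc"] = tested & (q < fdr)
    out["dvc_direction"] = np.where(
        ~out["is_dvc"], "", np.where(var_ra > var_oa, "hyper", "hypo")
    )
    return out


@dataclass
class OverlapTestResult:
    table: np.ndarray  # [[both, dmc_only], [dvc_only, neither]]
    fisher_p: float
    permutation_p: float
    n_permutations: int


def dmc_dvc_overlap_significance(
    dmc_set: set,
    dvc_set: set,
    universe_size: int,
    n_perm: int = 999,
    seed: int = 0,
) -> OverlapTestResult:
    """Enrichment of the DMC/DVC overlap against a common site universe.

    One-sided Fisher's exact test (equivalently the hypergeometric upper
    tail) plus a permutation test that redraws one set's membership
    uniformly from the universe; permutation p uses the add-one rule and
    so is floored at 1/(n_perm + 1).
    """
    a, b = len(dmc_set), len(dvc_set)
    both = len(dmc_set & dvc_set)
    union = len(dmc_set | dvc_set)
    if union > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    table = np.array(
        [[both, a - both], [b - both, universe_size - a - b + both]]
    )
    _, fisher_p = fisher_exact(table, alternative="greater")

    rng = np.random.default_rng(seed)
    # redrawing |A| sites without replacement makes the permuted overlap
    # hypergeometric; sample it directly
    perm_overlap = rng.hypergeometric(b, universe_size - b, a, size=n_perm)
    perm_p = (1 + int((perm_overlap >= both).sum())) / (n_perm + 1)
    return OverlapTestResult(table, float(fisher_p), float(perm_p), n_perm)


def _loo_nearest_centroid_ber(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out nearest-centroid balanced error rate.

    ``X`` is features x samples; ``y`` boolean (True = RA).
    """
    n = X.shape[1]
    sums = {g: X[:, y == g].sum(axis=1) for g in (True, False)}
    counts = {g: int((y == g).sum()) for g in (True, False)}
    errors = {True: 0, False: 0}
    for j in range(n):
        g = bool(y[j])
        cents = {}
        for h in (True, False):
            s, c = sums[h].copy(), counts[h]
            if h == g:
                s -= X[:, j]
                c -= 1
            cents[h] = s / c
        d_true = np.linalg.norm(X[:, j] - cents[True])
        d_false = np.linalg.norm(X[:, j] - cents[False])
        pred = d_true < d_false or (d_true == d_false and g)
        if pred != g:
            errors[g] += 1
    return 0.5 * (errors[True] / counts[True] + errors[False] / counts[False])


def balanced_error_classification(
    beta: np.ndarray,
    groups: np.ndarray,
    feature_sets: dict[str, np.ndarray],
    n_boot: int = 100,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Compare feature sets by leave-one-out nearest-centroid BER.

    ``beta`` is sites x samples; ``groups`` is an array of "RA"/"OA"
    labels; ``feature_sets`` maps a set name to site row indices.  For
    each set the observed BER and a distribution over ``n_boot`` seeded
    bootstrap resamples of the features are returned; the significance of
    each pairwise BER difference is assessed by label permutation.
    """
    y = np.asarray(groups) == "RA"
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need at least 3 samples per group")
    for name, idx in feature_sets.items():
        if len(idx) == 0:
            raise ValueError(f"feature set {name!r} is empty")
    rng = np.random.default_rng(seed)

    ber = {}
    ber_boot = {}
    for name, idx in feature_sets.items():
        idx = np.asarray(idx)
        ber[name] = _loo_nearest_centroid_ber(beta[idx], y)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            res = rng.choice(idx, size=len(idx), replace=True)
            boots[b] = _loo_nearest_centroid_ber(beta[res], y)
        ber_boot[name] = boots

    names = list(feature_sets)
    perm_p = {}
    if len(names) > 1 and n_perm > 0:
        perms = [rng.permutation(y) for _ in range(n_perm)]
        perm_ber = {
            name: np.array(
                [_loo_nearest_centroid_ber(beta[np.asarray(feature_sets[name])], yp)
                 for yp in perms]
            )
            for name in names
        }
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d_obs = ber[a] - ber[b]
                d_perm = perm_ber[a] - perm_ber[b]
                perm_p[(a, b)] = (1 + int((np.abs(d_perm) >= abs(d_obs)).sum())) / (
                    n_perm + 1
                )
    return {"ber": ber, "ber_boot": ber_boot, "perm_p": perm_p, "n_perm": n_perm}


def top_variable_cpg_clustering(
    samples: list[MethylomeSample], n_top: int = 500, min_cov: int = 1
) -> tuple[pd.DataFrame, np.ndarray]:
    """Hierarchically cluster samples on the most variable CpGs.

    Selects the ``n_top`` CpGs with the highest cross-sample beta
    standard deviation (ties at the boundary broken by genomic order) and
    returns the selected site table plus an average-linkage Euclidean
    linkage over samples.
    """
    sites, meth, cov = align_cohort(samples, min_cov=min_cov)
    if n_top > len(sites):
        raise ValueError(
            f"n_top = {n_top} exceeds the {len(sites)} commonly covered CpGs"
        )
    beta = meth / cov
    sd = beta.std(axis=0, ddof=1)
    order = np.argsort(-sd, kind="stable")  # stable: genomic order breaks ties
    sel = np.sort(order[:n_top])
    selected = sites.iloc[sel].copy()
    selected["sd"] = sd[sel]
    X = beta[:, sel]
    linkage = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    return selected, linkage
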
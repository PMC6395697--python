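"""Differential miRNA expression and methylation/target integration.

The differential-expression test is a documented simplification of the
classic DESeq procedure: median-of-ratios size factors, a pooled
method-of-moments dispersion per miRNA, and an exact-style test on the
two group count sums under fitted negative-binomial laws.  The analysis
thresholds — fold change > 2, unadjusted p < 0.05, expressed (nonzero)
in at least 50% of samples — define a DEmiR.

Integration: per DEmiR, every CpG inside the miRNA gene or up to 5 kb
strand-aware upstream is screened against normalized expression by
Spearman correlation (|rho| > 0.5, permutation p < 0.05); predicted
miRNA-target mRNA pairs are retained on negative Spearman correlation
with permutation p < 0.05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from ._permutation import perm_corr, perm_corr_many
from .types import GenomicInterval, MethylomeSample


def normalize_mirna(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization of a miRNA count matrix."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in sample(s): {list(zero.index)}")
    return counts / totals * 1e6


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (rows with any zero are ignored)."""
    log_counts = np.log(counts.replace(0, np.nan))
    log_geo = log_counts.mean(axis=1)
    ratios = log_counts.sub(log_geo, axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    if sf.isna().any():
        sf = sf.fillna(1.0)
    return sf


def _nb_pmf_vector(mean: float, var: float, kmax: int) -> np.ndarray:
    """pmf of counts 0..kmax under NB(mean, var) (Poisson if var <= mean)."""
    ks = np.arange(kmax + 1)
    if var <= mean * (1 + 1e-9):
        return poisson.pmf(ks, mean)
    r = mean * mean / (var - mean)
    p = mean / var
    return nbinom.pmf(ks, r, p)


def test_demir(
    counts: pd.DataFrame,
    groups: dict[str, str],
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
    expressed_fraction: float = 0.5,
) -> pd.DataFrame:
    """Differential miRNA expression between RA and OA.

    Fold change is computed on group means of CPM with a 0.5 pseudocount;
    the p value comes from the NB exact-style test described in the
    module docstring.  ``is_demir`` requires fold change > 2 (either
    direction), p < 0.05 and nonzero counts in at least 50% of samples.
    miRNAs with zero counts everywhere are excluded before testing.
    """
    ra_cols = [c for c in counts.columns if groups.get(c) == "RA"]
    oa_cols = [c for c in counts.columns if groups.get(c) == "OA"]
    if len(ra_cols) < 3 or len(oa_cols) < 3:
        raise ValueError("need at least 3 samples per group")
    counts = counts.loc[counts.sum(axis=1) > 0]
    sf = _size_factors(counts)
    q = counts / sf  # normalized counts

    mu_hat = q.mean(axis=1)
    var_hat = q.var(axis=1, ddof=1)
    s_ra, s_oa = sf[ra_cols].sum(), sf[oa_cols].sum()
    s2_ra = (sf[ra_cols] ** 2).sum()
    s2_oa = (sf[oa_cols] ** 2).sum()
    # pooled method-of-moments dispersion on normalized counts
    xi = float((1.0 / sf).mean())
    disp = np.maximum((var_hat - xi * mu_hat) / np.maximum(mu_hat**2, 1e-12), 0.0)

    p_vals = np.ones(len(counts))
    for i, mirna in enumerate(counts.index):
        k_ra = int(counts.loc[mirna, ra_cols].sum())
        k_oa = int(counts.loc[mirna, oa_cols].sum())
        k_tot = k_ra + k_oa
        if k_tot == 0:
            continue
        mu = mu_hat.loc[mirna]
        a = float(disp.loc[mirna])
        mean_a, var_a = mu * s_ra, mu * s_ra + a * mu * mu * s2_ra
        mean_b, var_b = mu * s_oa, mu * s_oa + a * mu * mu * s2_oa
        if k_tot > 200_000:  # normal approximation for very deep rows
            from scipy.stats import norm

            z = (k_ra - mean_a) / np.sqrt(var_a + var_b * (s_ra / s_oa) ** 2 + 1e-12)
            p_vals[i] = min(1.0, 2 * norm.sf(abs(z)))
            continue
        pa = _nb_pmf_vector(mean_a, var_a, k_tot)
        pb = _nb_pmf_vector(mean_b, var_b, k_tot)
        joint = pa * pb[::-1]  # P(K_A = a) P(K_B = k_tot - a)
        total = joint.sum()
        if total <= 0:
            p_vals[i] = 1.0
            continue
        obs = joint[k_ra]
        p_vals[i] = min(1.0, joint[joint <= obs * (1 + 1e-12)].sum() / total)

    # fold change on size-factor-normalized counts: median-of-ratios
    # factors are robust to composition shifts that distort per-million
    # scaling when many miRNAs move in the same direction
    pc = 0.5
    fc = (q[ra_cols].mean(axis=1) + pc) / (q[oa_cols].mean(axis=1) + pc)
    expr_frac = (counts > 0).mean(axis=1)
    is_demir = (
        ((fc > fold_threshold) | (fc < 1.0 / fold_threshold))
        & (p_vals < p_threshold)
        & (expr_frac >= expressed_fraction)
    )
    return pd.DataFrame(
        {
            "fold_change": fc,
            "p": p_vals,
            "expressed_fraction": expr_frac,
            "is_demir": is_demir,
        },
        index=counts.index,
    )


def _spearman_perm(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Spearman rho (average ranks) with a sample-permutation p value."""
    return perm_corr(x, y, n_perm, rng, method="spearman")


def cpgs_near_mirna(
    sample: MethylomeSample, mirna_gene: GenomicInterval, upstream: int = 5000
) -> np.ndarray:
    """Indices of CpGs inside the miRNA gene or <= 5 kb strand-aware upstream."""
    if mirna_gene.strand == "-":
        lo, hi = mirna_gene.start, mirna_gene.end + upstream
    else:
        lo, hi = mirna_gene.start - upstream, mirna_gene.end
    return np.flatnonzero(
        (sample.chrom == mirna_gene.chrom)
        & (sample.pos >= lo)
        & (sample.pos < hi)
    )


def correlate_cpg_mirna(
    samples: list[MethylomeSample],
    mirna_expr: pd.DataFrame,
    demirs: list[str],
    mirna_genes: list[GenomicInterval],
    upstream: int = 5000,
    n_perm: int = 999,
    seed: int = 0,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen CpGs near each DEmiR for methylation-expression correlation.

    ``mirna_expr`` must be normalized expression with sample columns
    matching the methylome sample ids.  Returns the tested pairs with
    Spearman rho, permutation p and the retained flag.
    """
    paired = [s for s in samples if s.sample_id in mirna_expr.columns]
    if len(paired) < 4:
        raise ValueError("need at least 4 paired samples")
    gene_by_name = {iv.name: iv for iv in mirna_genes}
    rng = np.random.default_rng(seed)
    rows = []
    betas = {s.sample_id: s.beta for s in paired}
    for mirna in demirs:
        iv = gene_by_name.get(mirna)
        if iv is None:
            warnings.warn(f"no gene coordinates for miRNA {mirna!r}; skipped",
                          stacklevel=2)
            continue
        ref = paired[0]
        idx = cpgs_near_mirna(ref, iv, upstream)
        if len(idx) == 0:
            continue
        y = mirna_expr.loc[mirna, [s.sample_id for s in paired]].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        X = np.stack([betas[s.sample_id][idx] for s in paired], axis=1)
        valid = ~np.isnan(X).any(axis=1)
        if not valid.any():
            continue
        idx = idx[valid]
        rho_all, p_all = perm_corr_many(X[valid], y, n_perm, rng, method="spearman")
        for i, rho, p in zip(idx, rho_all, p_all):
            if np.isnan(rho):
                continue
            rows.append(
                {
                    "chrom": str(ref.chrom[i]),
                    "pos": int(ref.pos[i]),
                    "mirna": mirna,
                    "spearman_rho": float(rho),
                    "perm_p": float(p),
                    "retained": abs(rho) > rho_threshold and p < p_threshold,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "mirna", "spearman_rho", "perm_p", "retained"]
    )


def correlate_mirna_targets(
    mirna_expr: pd.DataFrame,
    expr: pd.DataFrame,
    predicted_pairs: list[tuple[str, str]],
    demirs: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Retain predicted miRNA-target pairs with negative Spearman rho.

    A pair is retained when rho < 0 and permutation p < 0.05; pairs
    referencing unknown ids are skipped with a warning; constant vectors
    are skipped.
    """
    shared = [c for c in mirna_expr.columns if c in expr.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 paired samples")
    rng = np.random.default_rng(seed)
    rows = []
    for mirna, gene in predicted_pairs:
        if demirs is not None and mirna not in demirs:
            continue
        if mirna not in mirna_expr.index or gene not in expr.index:
            warnings.warn(f"unknown id in predicted pair ({mirna}, {gene}); skipped",
                          stacklevel=2)
            continue
        x = mirna_expr.loc[mirna, shared].to_numpy(dtype=float)
        y = expr.loc[gene, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rho, p = _spearman_perm(x, y, n_perm, rng)
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "spearman_rho": rho,
                "perm_p": p,
                "retained": rho < 0 and p < p_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "spearman_rho", "perm_p", "retained"]
    )
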
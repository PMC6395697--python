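"""LMR-to-expression integration.

Genes are ranked by a signal-to-noise ratio between the RA and OA
expression means; the set of genes lying on or within 5 kb downstream of
disease-specific LMRs is tested for enrichment at the top (or bottom) of
that ranking with a weighted Kolmogorov-Smirnov running sum (the classic
GSEA statistic, weight exponent 1), with a gene-label permutation null.
Individual LMR-gene pairs are additionally screened by Pearson
correlation between per-sample LMR methylation and expression
(|r| > 0.5, permutation p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._permutation import perm_corr
from .types import GeneModel, GenomicInterval, MethylomeSample


def rank_genes_by_de(expr: pd.DataFrame, groups: dict[str, str]) -> pd.Series:
    """Rank genes by signal-to-noise ratio (descending = RA-upregulated).

    SNR = (mean_RA - mean_OA) / (sd_RA + sd_OA), with each group SD
    floored at 0.2 * |group mean| (the usual GSEA guard against
    zero-variance genes).
    """
    ra_cols = [c for c in expr.columns if groups.get(c) == "RA"]
    oa_cols = [c for c in expr.columns if groups.get(c) == "OA"]
    if len(ra_cols) < 2 or len(oa_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    m1, m2 = expr[ra_cols].mean(axis=1), expr[oa_cols].mean(axis=1)
    s1 = np.maximum(expr[ra_cols].std(axis=1, ddof=1), 0.2 * m1.abs())
    s2 = np.maximum(expr[oa_cols].std(axis=1, ddof=1), 0.2 * m2.abs())
    denom = (s1 + s2).replace(0.0, 1e-12)
    snr = (m1 - m2) / denom
    return snr.sort_values(ascending=False, kind="mergesort")


def build_lmr_gene_set(
    specific_lmrs: list[GenomicInterval],
    gene_models: list[GeneModel],
    window: int = 5000,
) -> set[str]:
    """Genes carrying an LMR or lying within 5 kb downstream of one.

    A gene belongs to the set when an LMR overlaps its gene body, or when
    the gene's TSS is at most ``window`` bp downstream (strand-aware) of
    an LMR — i.e. the LMR sits within ``window`` bp upstream of the TSS.
    """
    out: set[str] = set()
    for g in gene_models:
        for lmr in specific_lmrs:
            if lmr.chrom != g.chrom:
                continue
            if lmr.overlaps(g.interval):
                out.add(g.name)
                break
            if g.strand == "+":
                gap = g.tss - lmr.end  # LMR upstream of a + gene
            else:
                gap = lmr.start - g.tss - 1
            if 0 <= gap < window:
                out.add(g.name)
                break
    return out


def running_enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running sum; returns (ES, running sum).

    Hits advance the sum by |score|^p normalized over in-set scores;
    misses retreat by 1/(N - N_hit).  ES is the extremum of the running
    sum (maximum deviation from zero, signed).  When the set covers the
    whole ranking there are no misses and ES is 0 by construction.
    """
    hit = np.array([g in gene_set for g in ranked_genes])
    n = len(ranked_genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    if n_hit == n:
        return 0.0, np.zeros(n)
    w = np.abs(np.asarray(scores, dtype=float)) ** weight_exponent
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:
        w_hit = hit.astype(float)
        total = float(n_hit)
    steps = w_hit / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


@dataclass
class EnrichmentResult:
    es: float  # raw running-sum extremum
    nes: float  # ES normalized by the mean same-sign permutation |ES|
    perm_p: float
    fdr_q: float
    perm_scores: np.ndarray
    n_perm: int


def lmr_target_gsea(
    ranking: pd.Series,
    gene_set: set[str],
    n_perm: int = 999,
    seed: int = 0,
) -> EnrichmentResult:
    """GSEA of an LMR-target gene set against a DE ranking.

    The null is gene-label permutation: random sets of the same size
    drawn from the ranked universe.  ``nes`` normalizes ES by the mean
    |ES| of same-sign permutations; ``fdr_q`` is the fraction of
    same-sign permutation NES values at least as extreme.
    """
    genes = list(ranking.index)
    in_universe = gene_set & set(genes)
    if not gene_set:
        raise ValueError("empty gene set")
    if not in_universe:
        raise ValueError("gene set is disjoint from the ranked universe")
    scores = ranking.to_numpy()
    es, _ = running_enrichment_score(genes, scores, in_universe)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    gene_arr = np.array(genes)
    for i in range(n_perm):
        rand_set = set(rng.choice(gene_arr, size=len(in_universe), replace=False))
        perm[i], _ = running_enrichment_score(genes, scores, rand_set)

    same_sign = perm[perm >= 0] if es >= 0 else -perm[perm < 0]
    if len(same_sign) == 0 or np.mean(np.abs(same_sign)) == 0:
        nes = 0.0
    else:
        nes = (abs(es) / np.mean(np.abs(same_sign))) * np.sign(es)
    perm_p = (1 + int((np.abs(perm) >= abs(es)).sum())) / (n_perm + 1)
    if len(same_sign) == 0:
        fdr_q = 1.0 / (n_perm + 1)
    else:
        perm_nes = np.abs(same_sign) / np.mean(np.abs(same_sign))
        fdr_q = max(
            float((perm_nes >= abs(nes)).mean()), 1.0 / (n_perm + 1)
        )
    return EnrichmentResult(es, float(nes), float(perm_p), float(fdr_q), perm, n_perm)


def lmr_mean_methylation(
    lmrs: list[GenomicInterval], samples: list[MethylomeSample]
) -> pd.DataFrame:
    """Per-sample mean beta inside each LMR (rows = LMRs, cols = samples)."""
    data = {}
    for s in samples:
        vals = []
        beta = s.beta
        for lmr in lmrs:
            on = (
                (s.chrom == lmr.chrom)
                & (s.pos >= lmr.start)
                & (s.pos < lmr.end)
            )
            vals.append(float(np.nanmean(beta[on])) if on.any() else np.nan)
        data[s.sample_id] = vals
    return pd.DataFrame(data, index=[lmr.name or f"lmr_{i}" for i, lmr in enumerate(lmrs)])


def nearest_gene_pairs(
    lmrs: list[GenomicInterval], gene_models: list[GeneModel]
) -> list[tuple[str, str]]:
    """(LMR id, gene id) pairs assigning each LMR to the gene with the
    closest TSS; ties broken by smaller genomic start."""
    pairs = []
    for i, lmr in enumerate(lmrs):
        center = lmr.midpoint
        candidates = [g for g in gene_models if g.chrom == lmr.chrom]
        if not candidates:
            continue
        best = min(
            candidates, key=lambda g: (abs(g.tss - center), g.interval.start)
        )
        pairs.append((lmr.name or f"lmr_{i}", best.name))
    return pairs


def correlate_lmr_expression(
    lmr_meth: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_perm: int = 999,
    seed: int = 0,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of LMR methylation with matched-gene expression.

    Per pair: Pearson r across paired samples, permutation p by sample
    shuffling (add-one rule); a pair is retained when |r| > 0.5 and
    p < 0.05.  Pairs with a constant methylation or expression vector are
    skipped with a reason.
    """
    shared = [c for c in lmr_meth.columns if c in expr.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 paired samples")
    rng = np.random.default_rng(seed)
    rows = []
    for lmr_id, gene_id in pairs:
        if lmr_id not in lmr_meth.index or gene_id not in expr.index:
            continue
        x = lmr_meth.loc[lmr_id, shared].to_numpy(dtype=float)
        y = expr.loc[gene_id, shared].to_numpy(dtype=float)
        good = ~(np.isnan(x) | np.isnan(y))
        x, y = x[good], y[good]
        if len(x) < 4 or np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {"lmr": lmr_id, "gene": gene_id, "pearson_r": np.nan,
                 "perm_p": np.nan, "retained": False, "direction": "",
                 "reason": "constant or insufficient data"}
            )
            continue
        r, p = perm_corr(x, y, n_perm, rng, method="pearson")
        retained = abs(r) > r_threshold and p < p_threshold
        rows.append(
            {"lmr": lmr_id, "gene": gene_id, "pearson_r": r, "perm_p": p,
             "retained": retained,
             "direction": ("negative" if r < 0 else "positive") if retained else "",
             "reason": ""}
        )
    return pd.DataFrame(rows)
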
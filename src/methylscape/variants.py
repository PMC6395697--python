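"""Rare-variant burden: candidate-gene selection and mutation-excess test.

Candidate genes carry variants in at least ``min_ra_samples`` RA samples
and in no OA sample.  Mutation excess per gene is tested under the
de novo mutation framework: with per-generation, per-copy mutation
probability mu and N sequenced individuals, the expected count is
lambda = 2 * N * mu (diploid copies) and the p value is the upper Poisson
tail P(X >= observed), significant at the conservative threshold 1e-8.
A point-biserial permutation test checks that carrier status is
independent of gene-body methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from ._permutation import perm_corr
from .types import GeneModel, MethylomeSample


def select_candidate_genes(
    variant_table: pd.DataFrame,
    groups: dict[str, str],
    min_ra_samples: int = 2,
) -> list[str]:
    """Genes with variants in >= ``min_ra_samples`` RA samples and 0 OA.

    ``variant_table`` needs columns (gene, sample, consequence).  The
    output shrinks (weakly) as ``min_ra_samples`` grows.
    """
    required = {"gene", "sample"}
    if not required.issubset(variant_table.columns):
        raise ValueError("variant table needs 'gene' and 'sample' columns")
    if variant_table.empty:
        return []
    tab = variant_table.copy()
    tab["group"] = tab["sample"].map(groups)
    if tab["group"].isna().any():
        missing = tab.loc[tab["group"].isna(), "sample"].unique()
        raise ValueError(f"samples with unknown group: {list(missing)[:5]}")
    per_gene = (
        tab.drop_duplicates(["gene", "sample"])
        .groupby(["gene", "group"])["sample"]
        .nunique()
        .unstack(fill_value=0)
    )
    n_ra = per_gene.get("RA", pd.Series(0, index=per_gene.index))
    n_oa = per_gene.get("OA", pd.Series(0, index=per_gene.index))
    keep = per_gene.index[(n_ra >= min_ra_samples) & (n_oa == 0)]
    return sorted(keep)


@dataclass(frozen=True)
class GeneMutationModel:
    gene: str
    mu: float  # per-generation, per-copy mutation probability
    n_individuals: int
    observed: int

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.observed < 0 or self.n_individuals < 1:
            raise ValueError("invalid counts")


@dataclass(frozen=True)
class ExcessTestResult:
    gene: str
    lambda_expected: float
    p_poisson: float
    significant: bool


def mutation_excess_test(
    model: GeneMutationModel, threshold: float = 1e-8
) -> ExcessTestResult:
    """Upper-tail Poisson test of mutation excess for one gene.

    lambda = 2 * N * mu; p = P(X >= observed).  ``observed = 0`` gives
    p = 1 and is never significant.
    """
    lam = 2.0 * model.n_individuals * model.mu
    if model.observed == 0:
        p = 1.0
    else:
        p = float(poisson.sf(model.observed - 1, lam))
    return ExcessTestResult(
        model.gene, lam, p, bool(p < threshold and model.observed >= 1)
    )


def test_gene_set_excess(
    variant_table: pd.DataFrame,
    mu_table: pd.DataFrame,
    groups: dict[str, str],
    genes: list[str] | None = None,
    group: str = "RA",
    threshold: float = 1e-8,
) -> pd.DataFrame:
    """Mutation-excess test for every gene (observed counts in one group)."""
    mu = mu_table.set_index("gene")["mu"]
    target_samples = [s for s, g in groups.items() if g == group]
    n = len(target_samples)
    tab = variant_table[variant_table["sample"].isin(target_samples)]
    obs = tab.groupby("gene").size()
    if genes is None:
        genes = sorted(mu.index)
    rows = []
    for gene in genes:
        if gene not in mu.index:
            continue
        res = mutation_excess_test(
            GeneMutationModel(gene, float(mu[gene]), n, int(obs.get(gene, 0))),
            threshold,
        )
        rows.append(
            {
                "gene": gene,
                "observed": int(obs.get(gene, 0)),
                "lambda_expected": res.lambda_expected,
                "p_poisson": res.p_poisson,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def methylation_independence_check(
    selected_genes: list[str],
    variant_table: pd.DataFrame,
    samples: list[MethylomeSample],
    gene_models: list[GeneModel],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation of variant-carrier status with gene-body methylation.

    Per gene: point-biserial correlation between carrier status (0/1 per
    sample) and the sample's mean gene-body beta, with a two-sided
    permutation p.  Genes where every sample (or none) is a carrier are
    skipped.
    """
    model_by_name = {g.name: g for g in gene_models}
    carriers = (
        variant_table.drop_duplicates(["gene", "sample"])
        .groupby("gene")["sample"]
        .apply(set)
        .to_dict()
    )
    rng = np.random.default_rng(seed)
    rows = []
    for gene in selected_genes:
        gm = model_by_name.get(gene)
        if gm is None:
            continue
        status = np.array(
            [1.0 if s.sample_id in carriers.get(gene, set()) else 0.0 for s in samples]
        )
        if status.min() == status.max():
            rows.append({"gene": gene, "r": np.nan, "p": np.nan, "skipped": True})
            continue
        meth = []
        for s in samples:
            on = (
                (s.chrom == gm.chrom)
                & (s.pos >= gm.interval.start)
                & (s.pos < gm.interval.end)
            )
            meth.append(float(np.nanmean(s.beta[on])) if on.any() else np.nan)
        meth = np.array(meth)
        good = ~np.isnan(meth)
        if good.sum() < 4 or np.std(meth[good]) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan, "skipped": True})
            continue
        x, y = status[good], meth[good]
        r, p = perm_corr(y, x, n_perm, rng, method="pearson")
        rows.append({"gene": gene, "r": r, "p": p, "skipped": False})
    return pd.DataFrame(rows, columns=["gene", "r", "p", "skipped"])
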
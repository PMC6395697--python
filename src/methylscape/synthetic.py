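"""Synthetic two-group (RA vs OA) methylome cohort generator.

The generator emulates the statistical structure the analysis assumes,
with full ground truth, so every downstream stage can be tested without
patient data:

* a single synthetic chromosome whose CpG spacing is i.i.d. geometric
  (mean 100 bp), reproducing realistic CpG density without a reference;
* a polarized ("bimodal") background — most CpGs nearly fully methylated,
  a small scattered fraction unmethylated;
* planted PMDs (disordered intermediate methylation, dispersed
  symmetric-Beta emissions per sample), UMRs (>= 30 unmethylated CpGs,
  CpG-island-like) and LMRs (< 30 low-methylated CpGs, enhancer-like),
  either shared between groups or specific to one group with configurable
  penetrance;
* planted differentially methylated CpGs (DMCs, group mean shift delta)
  and differentially variable CpGs (DVCs, group variance ratio);
* gene models whose expression is negatively coupled to the methylation
  of an assigned group-specific LMR;
* miRNA genes whose counts scale with promoter/gene-body methylation;
* per-gene variant tables with planted mutation-excess genes.

Coverage is Poisson(mean_cov) truncated at >= 1; methylated counts are
Binomial(cov, beta).  All randomness flows from ``CohortConfig.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeneModel, GenomicInterval, MethylomeSample, MethylscapeError

CHROM = "chrS"


class ConfigError(MethylscapeError):
    """Invalid or inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Cohort layout and effect sizes.

    Defaults give a compact cohort (3 vs 3, 1e5 CpGs at 22x mean
    coverage) that preserves the data structure of a WGBS case/control
    comparison at desk scale.
    """

    n_ra: int = 3
    n_oa: int = 3
    n_cpg: int = 100_000
    mean_cov: float = 22.0
    cpg_spacing_mean: float = 100.0

    # planted regions (counts and sizes in CpGs)
    n_pmd: int = 2
    pmd_cpgs: int = 1500
    n_umr: int = 40
    umr_cpgs: int = 40
    n_lmr_shared: int = 60
    n_lmr_ra: int = 12
    n_lmr_oa: int = 8
    lmr_cpgs: int = 10
    mirna_region_cpgs: int = 65  # broad RA-specific regions carrying miRNAs
    penetrance: float = 1.0
    min_gap_cpgs: int = 40

    # emission parameters
    background_low_frac: float = 0.05  # scattered unmethylated CpGs
    lmr_mean_range: tuple[float, float] = (0.15, 0.35)
    bio_jitter_kappa: float | None = None  # optional extra-binomial noise

    # planted single-CpG effects
    n_dmc: int = 50
    dmc_delta: float = 0.3
    dmc_base: float = 0.03
    n_dvc: int = 50
    dvc_var_ratio: float = 100.0

    # expression / miRNA / variants
    n_genes: int = 200
    n_coupled_genes: int = 8
    expr_coupling: float = 4.0  # log2 units per beta unit, negative direction
    expr_noise_sd: float = 0.25
    n_mirna: int = 60
    n_coupled_mirna: int = 8
    mirna_coupling: float = 3.0
    mirna_dispersion: float = 0.05
    n_de_mirna: int = 5
    de_fold: float = 4.0
    n_var_genes: int = 100
    n_excess_genes: int = 3
    mu_variant: float = 1e-5
    excess_factor: float = 2e5  # per-sample excess rate 2*mu*factor = 4

    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_ra", "n_oa", "n_cpg"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.dmc_delta < 1.0):
            raise ConfigError("dmc_delta must lie in (0, 1)")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ConfigError("penetrance must lie in [0, 1]")
        if self.mu_variant <= 0:
            raise ConfigError("mu_variant must be positive")
        if self.n_lmr_ra < self.n_coupled_genes:
            raise ConfigError(
                "need n_lmr_ra >= n_coupled_genes (gene couplings attach to "
                "RA-specific LMRs)"
            )
        n_regions = (
            self.n_pmd + self.n_umr + self.n_lmr_shared + self.n_lmr_ra
            + self.n_lmr_oa + self.n_coupled_mirna
        )
        needed = (
            self.n_pmd * self.pmd_cpgs
            + self.n_umr * self.umr_cpgs
            + (self.n_lmr_shared + self.n_lmr_ra + self.n_lmr_oa) * self.lmr_cpgs
            + self.n_coupled_mirna * self.mirna_region_cpgs
            + (n_regions + 1) * self.min_gap_cpgs
        )
        if needed > self.n_cpg:
            raise ConfigError(
                f"planted regions need {needed} CpGs but genome has {self.n_cpg}"
            )

    def sample_ids(self) -> list[str]:
        return [f"RA_{i + 1:02d}" for i in range(self.n_ra)] + [
            f"OA_{i + 1:02d}" for i in range(self.n_oa)
        ]


@dataclass(frozen=True)
class PlantedRegion:
    region_id: str
    klass: str  # PMD | UMR | LMR
    group: str  # shared | RA | OA
    cpg_start: int  # CpG index slice [cpg_start, cpg_end)
    cpg_end: int
    interval: GenomicInterval
    carriers: tuple[str, ...]  # samples hypomethylated in this region


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort (the acceptance surface)."""

    chrom: str
    positions: np.ndarray
    sample_ids: list[str]
    groups: dict[str, str]
    regions: list[PlantedRegion]
    dmc: pd.DataFrame  # columns: pos, sign (+1 = RA higher), cpg_index
    dvc_pos: np.ndarray
    region_meth: pd.DataFrame  # true per-sample mean beta per planted region
    genes: list[GeneModel]
    coupled_genes: dict[str, str]  # gene name -> region_id
    mirna_genes: list[GenomicInterval]
    coupled_mirnas: dict[str, str]  # miRNA id -> region_id
    variant_genes: list[str]
    excess_genes: list[str]

    def regions_of(self, klass: str, group: str | None = None) -> list[PlantedRegion]:
        return [
            r
            for r in self.regions
            if r.klass == klass and (group is None or r.group == group)
        ]

    def true_intervals(self, sample_id: str, klass: str) -> list[GenomicInterval]:
        """Intervals of a class truly hypomethylated/disordered in a sample."""
        out = []
        for r in self.regions:
            if r.klass != klass:
                continue
            if r.group == "shared" or sample_id in r.carriers:
                out.append(r.interval)
        return out


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_methylome_cohort(
    config: CohortConfig,
) -> tuple[list[MethylomeSample], CohortTruth]:
    """Simulate per-CpG methylation calls for the whole cohort.

    Returns the samples (RA first, then OA) and the ground truth.
    Byte-identical output is guaranteed for identical configs.
    """
    config.validate()
    rng = _stage_rng(config.rng_seed, 0)
    n = config.n_cpg
    sample_ids = config.sample_ids()
    groups = {s: ("RA" if s.startswith("RA") else "OA") for s in sample_ids}
    ra_ids = [s for s in sample_ids if groups[s] == "RA"]
    oa_ids = [s for s in sample_ids if groups[s] == "OA"]
    n_samples = len(sample_ids)

    # --- genome layout -------------------------------------------------
    spacings = rng.geometric(1.0 / config.cpg_spacing_mean, size=n)
    positions = 1000 + np.cumsum(spacings)

    specs: list[tuple[str, str, int]] = (
        [("PMD", "shared", config.pmd_cpgs)] * config.n_pmd
        + [("UMR", "shared", config.umr_cpgs)] * config.n_umr
        + [("LMR", "shared", config.lmr_cpgs)] * config.n_lmr_shared
        + [("LMR", "RA", config.lmr_cpgs)] * config.n_lmr_ra
        + [("LMR", "OA", config.lmr_cpgs)] * config.n_lmr_oa
        # broad RA-specific hypomethylated regions hosting coupled miRNAs
        + [("UMR", "RA", config.mirna_region_cpgs)] * config.n_coupled_mirna
    )
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    n_gaps = len(specs) + 1
    spare = n - sum(s[2] for s in specs) - n_gaps * config.min_gap_cpgs
    extra = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))

    counters = {"PMD": 0, "UMR": 0, "LMR": 0}
    slices: list[tuple[str, str, int, int]] = []
    cursor = 0
    for i, (klass, group, size) in enumerate(specs):
        cursor += config.min_gap_cpgs + int(extra[i])
        slices.append((klass, group, cursor, cursor + size))
        cursor += size

    in_region = np.zeros(n, dtype=bool)
    for _, _, a, b in slices:
        in_region[a:b] = True

    # --- baseline methylation (shared across samples) ------------------
    beta0 = rng.beta(20, 2, size=n)  # polarized high mode
    low_bg = (~in_region) & (rng.random(n) < config.background_low_frac)
    beta0[low_bg] = rng.beta(2, 20, size=int(low_bg.sum()))

    pmd_mask = np.zeros(n, dtype=bool)
    beta_low = np.full(n, np.nan)  # carrier-state baseline for specific LMRs
    regions: list[PlantedRegion] = []
    lo, hi = config.lmr_mean_range
    kappa = 50.0
    for klass, group, a, b in slices:
        size = b - a
        if klass == "PMD":
            pmd_mask[a:b] = True
        elif group == "shared":
            if klass == "UMR":
                beta0[a:b] = rng.beta(2, 38, size=size)  # low mode ~0.05
            else:
                mu = rng.uniform(lo, hi)
                beta0[a:b] = rng.beta(mu * kappa, (1 - mu) * kappa, size=size)
        else:  # group-specific: high baseline, low state for carriers only
            beta0[a:b] = rng.beta(20, 2, size=size)
            if klass == "UMR":
                beta_low[a:b] = rng.beta(2, 38, size=size)
            else:
                mu = rng.uniform(lo, hi)
                beta_low[a:b] = rng.beta(mu * kappa, (1 - mu) * kappa, size=size)
        idx = counters[klass]
        counters[klass] += 1
        target = ra_ids if group == "RA" else oa_ids if group == "OA" else []
        if group == "shared":
            carriers = tuple(sample_ids)
        else:
            flags = rng.random(len(target)) < config.penetrance
            carriers = tuple(s for s, f in zip(target, flags) if f)
        regions.append(
            PlantedRegion(
                f"{klass}_{group}_{idx:03d}",
                klass,
                group,
                a,
                b,
                GenomicInterval(
                    CHROM, int(positions[a]), int(positions[b - 1]) + 1,
                    name=f"{klass}_{group}_{idx:03d}",
                ),
                carriers,
            )
        )

    # --- planted single-CpG effects ------------------------------------
    free = np.flatnonzero(~in_region & ~low_bg)
    rng.shuffle(free)
    picked: list[int] = []
    taken = np.zeros(n, dtype=bool)
    need = config.n_dmc + config.n_dvc
    for i in free:
        if len(picked) == need:
            break
        a, b = max(0, i - 5), min(n, i + 6)
        if not taken[a:b].any():
            picked.append(int(i))
            taken[i] = True
    if len(picked) < need:
        raise ConfigError("genome too small to place requested DMCs/DVCs")
    dmc_idx = np.sort(np.array(picked[: config.n_dmc], dtype=int))
    dvc_idx = np.sort(np.array(picked[config.n_dmc :], dtype=int))
    dmc_sign = np.where(np.arange(len(dmc_idx)) % 2 == 0, 1, -1)

    # --- per-sample true betas -----------------------------------------
    B = np.tile(beta0, (n_samples, 1))
    ra_rows = np.array([groups[s] == "RA" for s in sample_ids])
    for si, sid in enumerate(sample_ids):
        npmd = int(pmd_mask.sum())
        if npmd:
            B[si, pmd_mask] = rng.beta(1.5, 1.5, size=npmd)
    for r in regions:
        if r.group == "shared" or r.klass == "PMD":
            continue
        for si, sid in enumerate(sample_ids):
            if sid in r.carriers:
                B[si, r.cpg_start : r.cpg_end] = beta_low[r.cpg_start : r.cpg_end]
    base, delta = config.dmc_base, config.dmc_delta
    for j, i in enumerate(dmc_idx):
        high, lowv = base + delta, base
        if dmc_sign[j] > 0:  # RA hypermethylated
            B[ra_rows, i] = high
            B[~ra_rows, i] = lowv
        else:
            B[ra_rows, i] = lowv
            B[~ra_rows, i] = high
    k_oa = 198.0
    var_oa = 0.25 / (k_oa + 1)
    k_ra = max(0.25 / (var_oa * config.dvc_var_ratio) - 1, 0.5)
    for i in dvc_idx:
        B[ra_rows, i] = rng.beta(0.5 * k_ra, 0.5 * k_ra, size=int(ra_rows.sum()))
        B[~ra_rows, i] = rng.beta(0.5 * k_oa, 0.5 * k_oa, size=int((~ra_rows).sum()))
    if config.bio_jitter_kappa:
        k = config.bio_jitter_kappa
        Bc = np.clip(B, 0.01, 0.99)
        B = rng.beta(Bc * k, (1 - Bc) * k)

    # --- reads ----------------------------------------------------------
    cov = rng.poisson(config.mean_cov, size=(n_samples, n))
    cov[cov == 0] = 1  # zero-coverage CpGs carry no information
    meth = rng.binomial(cov, np.clip(B, 1e-4, 1 - 1e-4))

    chrom_arr = np.full(n, CHROM, dtype=object)
    samples = [
        MethylomeSample(sid, groups[sid], chrom_arr, positions.copy(),
                        cov[si], meth[si])
        for si, sid in enumerate(sample_ids)
    ]

    region_meth = pd.DataFrame(
        {
            sid: [float(B[si, r.cpg_start : r.cpg_end].mean()) for r in regions]
            for si, sid in enumerate(sample_ids)
        },
        index=[r.region_id for r in regions],
    )

    # --- gene models -----------------------------------------------------
    ra_lmrs = [r for r in regions if r.klass == "LMR" and r.group == "RA"]
    genes: list[GeneModel] = []
    coupled_genes: dict[str, str] = {}
    genome_end = int(positions[-1]) + 10_000
    for gi in range(config.n_genes):
        name = f"gene_{gi:04d}"
        if gi < config.n_coupled_genes:
            reg = ra_lmrs[gi]
            tss = reg.interval.end + int(rng.integers(1000, 4000))
            start, end, strand = tss, tss + 8000, "+"
            exon_starts = (start, start + 2000, start + 6000)
            exon_ends = (start + 500, start + 2500, end)
            coupled_genes[name] = reg.region_id
        else:
            start = int(rng.integers(0, genome_end - 20_000))
            length = int(rng.integers(5000, 20_000))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(np.arange(1, 2 * n_ex), 2 * n_ex - 2,
                                        replace=False))
            cuts = [start] + [start + int(b * length / (2 * n_ex)) for b in bounds] + [end]
            exon_starts = tuple(cuts[0::2][:n_ex])
            exon_ends = tuple(cuts[1::2][:n_ex])
        genes.append(
            GeneModel(
                GenomicInterval(CHROM, start, end, name, strand),
                tuple(exon_starts), tuple(exon_ends),
            )
        )

    # --- miRNA genes -----------------------------------------------------
    mirna_genes: list[GenomicInterval] = []
    coupled_mirnas: dict[str, str] = {}
    mirna_regions = [r for r in regions if r.klass == "UMR" and r.group == "RA"]
    for mi in range(config.n_mirna):
        name = f"mir_{mi:03d}"
        if mi < config.n_coupled_mirna:
            # miRNA gene at the downstream end of its broad hypomethylated
            # region, so the 5 kb upstream window stays inside the region
            reg = mirna_regions[mi]
            iv = GenomicInterval(
                CHROM, max(0, reg.interval.end - 1500), reg.interval.end + 500,
                name, "+",
            )
            coupled_mirnas[name] = reg.region_id
        else:
            start = int(rng.integers(0, genome_end - 3000))
            iv = GenomicInterval(CHROM, start, start + 2000, name, "+")
        mirna_genes.append(iv)

    decoy_names = [g.name for g in genes if g.name not in coupled_genes]
    variant_genes = decoy_names[-config.n_var_genes :]
    excess_genes = variant_genes[: config.n_excess_genes]

    truth = CohortTruth(
        chrom=CHROM,
        positions=positions,
        sample_ids=sample_ids,
        groups=groups,
        regions=regions,
        dmc=pd.DataFrame(
            {
                "pos": positions[dmc_idx],
                "sign": dmc_sign,
                "cpg_index": dmc_idx,
            }
        ),
        dvc_pos=positions[dvc_idx],
        region_meth=region_meth,
        genes=genes,
        coupled_genes=coupled_genes,
        mirna_genes=mirna_genes,
        coupled_mirnas=coupled_mirnas,
        variant_genes=variant_genes,
        excess_genes=excess_genes,
    )
    return samples, truth


def simulate_expression_profiles(
    config: CohortConfig, truth: CohortTruth
) -> pd.DataFrame:
    """Gene expression (log2 intensity) matrix, genes x samples.

    Coupled genes depend linearly (negatively, slope ``expr_coupling``) on
    the per-sample mean methylation of their assigned LMR, plus Gaussian
    noise; all other genes are uncoupled log-normal intensities.
    """
    rng = _stage_rng(config.rng_seed, 2)
    n_samples = len(truth.sample_ids)
    data = np.empty((len(truth.genes), n_samples))
    for gi, gene in enumerate(truth.genes):
        base = rng.normal(7.0, 1.0)
        noise = rng.normal(0.0, config.expr_noise_sd, size=n_samples)
        if gene.name in truth.coupled_genes:
            reg_id = truth.coupled_genes[gene.name]
            meth = truth.region_meth.loc[reg_id].to_numpy()
            data[gi] = base + config.expr_coupling * (0.5 - meth) + noise
        else:
            data[gi] = base + noise
    return pd.DataFrame(data, index=[g.name for g in truth.genes],
                        columns=truth.sample_ids)


def simulate_mirna_counts(
    config: CohortConfig, truth: CohortTruth
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Negative-binomial miRNA counts plus the miRNA gene BED intervals.

    Coupled miRNAs' expected counts scale as ``2**(-c * (meth - 0.5))``
    with the true mean methylation of their planted region; the first
    ``n_de_mirna`` uncoupled miRNAs receive a pure RA fold change.
    Library sizes vary at most two-fold.
    """
    rng = _stage_rng(config.rng_seed, 3)
    n_samples = len(truth.sample_ids)
    lib = rng.uniform(0.7, 1.4, size=n_samples)
    ra_rows = np.array([truth.groups[s] == "RA" for s in truth.sample_ids])
    disp = config.mirna_dispersion
    data = np.empty((len(truth.mirna_genes), n_samples), dtype=np.int64)
    uncoupled_seen = 0
    for mi, iv in enumerate(truth.mirna_genes):
        base = float(np.exp(rng.uniform(np.log(20), np.log(2000))))
        mu = np.full(n_samples, base)
        if iv.name in truth.coupled_mirnas:
            reg_id = truth.coupled_mirnas[iv.name]
            meth = truth.region_meth.loc[reg_id].to_numpy()
            mu = base * np.power(2.0, -config.mirna_coupling * (meth - 0.5))
        else:
            if uncoupled_seen < config.n_de_mirna:
                mu = np.where(ra_rows, base * config.de_fold, base)
            uncoupled_seen += 1
        mu = mu * lib
        if disp < 1e-8:
            data[mi] = rng.poisson(mu)
        else:
            r = 1.0 / disp
            data[mi] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(data, index=[iv.name for iv in truth.mirna_genes],
                          columns=truth.sample_ids)
    return counts, truth.mirna_genes


def simulate_variant_tables(
    config: CohortConfig, truth: CohortTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample variant table and per-gene mutation probability table.

    Baseline per-gene, per-sample variant counts are Poisson(2*mu);
    planted excess genes get the inflated rate ``mu * excess_factor`` in
    RA samples only.
    """
    config.validate()
    rng = _stage_rng(config.rng_seed, 4)
    if truth is not None:
        gene_names = truth.variant_genes
        excess = set(truth.excess_genes)
        sample_ids = truth.sample_ids
        groups = truth.groups
    else:
        gene_names = [f"vgene_{i:04d}" for i in range(config.n_var_genes)]
        excess = set(gene_names[: config.n_excess_genes])
        sample_ids = config.sample_ids()
        groups = {s: ("RA" if s.startswith("RA") else "OA") for s in sample_ids}

    mu = config.mu_variant
    rows = []
    for gene in gene_names:
        for sid in sample_ids:
            rate = 2.0 * mu
            if gene in excess and groups[sid] == "RA":
                rate = 2.0 * mu * config.excess_factor
            k = rng.poisson(rate)
            rows.extend({"gene": gene, "sample": sid, "consequence": "missense"}
                        for _ in range(int(k)))
    variants = pd.DataFrame(rows, columns=["gene", "sample", "consequence"])
    mu_table = pd.DataFrame({"gene": gene_names, "mu": mu})
    return variants, mu_table


# ---------------------------------------------------------------------------
# recovery metrics


def base_level_f1(
    called: list[GenomicInterval], truth: list[GenomicInterval]
) -> float:
    """Base-pair-level F1 between a called and a true interval set."""
    from .types import total_bp, total_overlap_bp

    called_bp, truth_bp = total_bp(called), total_bp(truth)
    if called_bp == 0 and truth_bp == 0:
        return 1.0
    if called_bp == 0 or truth_bp == 0:
        return 0.0
    tp = total_overlap_bp(called, truth)
    precision = tp / called_bp
    recall = tp / truth_bp
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
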
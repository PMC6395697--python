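"""Stage orchestration with a single config, seeded determinism and a manifest.

Stages run in dependency order::

    simulate -> segment -> specific-lmrs -> site-stats -> gsea -> mirna -> variants

Each stage reads its inputs from files written by upstream stages, so a
stage can be rerun in isolation; a missing prerequisite raises
:class:`PrerequisiteError` naming the file.  A ``manifest.json`` with
parameters, seed and sha256 checksums of every output is written at the
end; identical config + seed gives byte-identical outputs and hence
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, io_formats, mirna as mirna_mod, regions, site_stats, variants
from .segmentation import segment_sample
from .synthetic import (
    CohortConfig,
    simulate_expression_profiles,
    simulate_methylome_cohort,
    simulate_mirna_counts,
    simulate_variant_tables,
    _stage_rng,
)
from .types import MethylscapeError

STAGES = (
    "simulate",
    "segment",
    "specific-lmrs",
    "site-stats",
    "gsea",
    "mirna",
    "variants",
)


class PrerequisiteError(MethylscapeError):
    """A requested stage is missing an upstream output."""


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    cohort: CohortConfig
    seed: int = 0
    window_cpgs: int = 101
    fdr_bound: float = 0.05
    min_cov: int = 5
    n_perm: int = 999
    kmeans_k: int = 2

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.cohort.rng_seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path, outdir, seed: int | None = None) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.get("cohort", {}))
        kwargs = {k: v for k, v in raw.items() if k != "cohort"}
        if seed is not None:
            kwargs["seed"] = seed
        return cls(outdir=Path(outdir), cohort=cohort, **kwargs)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PrerequisiteError(
            f"stage {stage!r} needs {path.name}; run its upstream stage first"
        )
    return path


def _read_groups(outdir: Path, stage: str) -> dict[str, str]:
    path = _require(outdir / "groups.tsv", stage)
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def _load_cohort(cfg: PipelineConfig, stage: str):
    groups = _read_groups(cfg.outdir, stage)
    samples = []
    for sid in sorted(groups):
        cov = _require(cfg.outdir / f"{sid}.cov", stage)
        samples.append(io_formats.read_bismark_coverage(cov, sid, groups[sid]))
    return samples, groups


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    samples, truth = simulate_methylome_cohort(cfg.cohort)
    written = []
    for s in samples:
        p = out / f"{s.sample_id}.cov"
        io_formats.write_bismark_coverage(s, p)
        written.append(p)
    gp = out / "groups.tsv"
    pd.DataFrame(
        {"sample": [s.sample_id for s in samples], "group": [s.group for s in samples]}
    ).to_csv(gp, sep="\t", index=False)
    written.append(gp)

    tp = out / "truth_regions.bed"
    io_formats.write_bed(
        [dataclasses.replace(r.interval, name=f"{r.klass}:{r.group}")
         for r in truth.regions],
        tp,
    )
    written.append(tp)

    expr = simulate_expression_profiles(cfg.cohort, truth)
    ep = out / "expression.tsv"
    io_formats.write_matrix_tsv(expr, ep)
    written.append(ep)

    counts, mirna_genes = simulate_mirna_counts(cfg.cohort, truth)
    cp = out / "mirna_counts.tsv"
    io_formats.write_matrix_tsv(counts, cp)
    mb = out / "mirna_genes.bed"
    io_formats.write_bed(mirna_genes, mb)
    written += [cp, mb]

    gb = out / "genes.bed12"
    io_formats.write_gene_models(truth.genes, gb)
    written.append(gb)

    var_tab, mu_tab = simulate_variant_tables(cfg.cohort, truth)
    vp, mp = out / "variants.tsv", out / "mutation_mu.tsv"
    var_tab.to_csv(vp, sep="\t", index=False)
    mu_tab.to_csv(mp, sep="\t", index=False)
    written += [vp, mp]

    # predicted miRNA-target pairs: each miRNA paired with two genes
    rng = _stage_rng(cfg.cohort.rng_seed, 5)
    gene_names = [g.name for g in truth.genes]
    pairs = [
        {"mirna": iv.name, "gene": gene_names[int(rng.integers(len(gene_names)))]}
        for iv in truth.mirna_genes
        for _ in range(2)
    ]
    pp = out / "predicted_pairs.tsv"
    pd.DataFrame(pairs).to_csv(pp, sep="\t", index=False)
    written.append(pp)
    return written


def stage_segment(cfg: PipelineConfig) -> list[Path]:
    samples, _ = _load_cohort(cfg, "segment")
    written = []
    for s in samples:
        segs, _cut = segment_sample(
            s, window_cpgs=cfg.window_cpgs, fdr_bound=cfg.fdr_bound, seed=cfg.seed
        )
        p = cfg.outdir / f"segments_{s.sample_id}.bed"
        io_formats.write_bed(segs, p)
        written.append(p)
    return written


def _load_lmrs(cfg: PipelineConfig, stage: str):
    groups = _read_groups(cfg.outdir, stage)
    lmrs = {}
    for sid in sorted(groups):
        p = _require(cfg.outdir / f"segments_{sid}.bed", stage)
        lmrs[sid] = [iv for iv in io_formats.read_bed(p) if iv.name == "LMR"]
    return lmrs, groups


def stage_specific_lmrs(cfg: PipelineConfig) -> list[Path]:
    lmrs, groups = _load_lmrs(cfg, "specific-lmrs")
    samples, _ = _load_cohort(cfg, "specific-lmrs")
    ra_set, oa_set = regions.call_group_specific_lmrs(lmrs, groups)
    out = cfg.outdir
    written = []
    for rs, tag in ((ra_set, "ra"), (oa_set, "oa")):
        p = out / f"specific_lmrs_{tag}.bed"
        io_formats.write_bed(rs.regions, p)
        written.append(p)
    jmat, linkage = regions.jaccard_sample_clustering(lmrs)
    jp = out / "jaccard.tsv"
    jmat.to_csv(jp, sep="\t")
    np_ = out / "jaccard_dendrogram.nwk"
    np_.write_text(regions.linkage_to_newick(linkage, list(jmat.index)) + "\n")
    written += [jp, np_]
    if len(ra_set.regions):
        _, labels = regions.profile_and_cluster_lmrs(
            ra_set, samples, k=cfg.kmeans_k, seed=cfg.seed
        )
        cp = out / "profile_clusters_ra.tsv"
        pd.DataFrame(
            {"region": [r.name for r in ra_set.regions], "cluster": labels}
        ).to_csv(cp, sep="\t", index=False)
        written.append(cp)
    genes_path = out / "genes.bed12"
    if genes_path.exists():
        gene_models = io_formats.read_gene_models(genes_path)
        ann = regions.annotate_lmr_position(ra_set.regions, gene_models)
        ap = out / "annotation_ra.tsv"
        pd.DataFrame(
            {
                "region": [r.region.name for r in ann],
                "category": [r.category for r in ann],
                "gene": [r.gene or "" for r in ann],
                "intron_index": [r.intron_index if r.intron_index else "" for r in ann],
                "relative_position": [
                    f"{r.relative_position:.4f}" if r.relative_position is not None else ""
                    for r in ann
                ],
            }
        ).to_csv(ap, sep="\t", index=False)
        written.append(ap)
    return written


def stage_site_stats(cfg: PipelineConfig) -> list[Path]:
    samples, _ = _load_cohort(cfg, "site-stats")
    dmc = site_stats.test_dmc(samples, min_cov=cfg.min_cov)
    dvc = site_stats.test_dvc(samples, min_cov=cfg.min_cov)
    out = cfg.outdir
    dp, vp = out / "dmc.tsv", out / "dvc.tsv"
    dmc.to_csv(dp, sep="\t", index=False, float_format="%.6g")
    dvc.to_csv(vp, sep="\t", index=False, float_format="%.6g")
    dmc_set = set(dmc.loc[dmc["is_dmc"], "pos"])
    dvc_set = set(dvc.loc[dvc["is_dvc"], "pos"])
    res = site_stats.dmc_dvc_overlap_significance(
        dmc_set, dvc_set, universe_size=len(dmc), n_perm=cfg.n_perm, seed=cfg.seed
    )
    op = out / "dmc_dvc_overlap.json"
    op.write_text(
        json.dumps(
            {
                "table": res.table.tolist(),
                "fisher_p": res.fisher_p,
                "permutation_p": res.permutation_p,
                "n_permutations": res.n_permutations,
            },
            indent=2,
        )
        + "\n"
    )
    return [dp, vp, op]


def stage_gsea(cfg: PipelineConfig) -> list[Path]:
    out = cfg.outdir
    expr = io_formats.read_matrix_tsv(_require(out / "expression.tsv", "gsea"))
    gene_models = io_formats.read_gene_models(_require(out / "genes.bed12", "gsea"))
    groups = _read_groups(out, "gsea")
    samples, _ = _load_cohort(cfg, "gsea")
    ranking = enrichment.rank_genes_by_de(expr, groups)
    rows = []
    pair_frames = []
    for tag in ("ra", "oa"):
        bed = _require(out / f"specific_lmrs_{tag}.bed", "gsea")
        lmrs = io_formats.read_bed(bed)
        if not lmrs:
            continue
        gene_set = enrichment.build_lmr_gene_set(lmrs, gene_models)
        if gene_set:
            res = enrichment.lmr_target_gsea(
                ranking, gene_set, n_perm=cfg.n_perm, seed=cfg.seed
            )
            rows.append(
                {
                    "set": tag.upper(), "n_genes": len(gene_set), "es": res.es,
                    "nes": res.nes, "perm_p": res.perm_p, "fdr_q": res.fdr_q,
                }
            )
        meth = enrichment.lmr_mean_methylation(lmrs, samples)
        pairs = enrichment.nearest_gene_pairs(lmrs, gene_models)
        pair_frames.append(
            enrichment.correlate_lmr_expression(
                meth, expr, pairs, n_perm=cfg.n_perm, seed=cfg.seed
            ).assign(set=tag.upper())
        )
    gp = out / "gsea.tsv"
    pd.DataFrame(rows).to_csv(gp, sep="\t", index=False, float_format="%.6g")
    lp = out / "lmr_gene_pairs.tsv"
    (pd.concat(pair_frames) if pair_frames else pd.DataFrame()).to_csv(
        lp, sep="\t", index=False, float_format="%.6g"
    )
    return [gp, lp]


def stage_mirna(cfg: PipelineConfig) -> list[Path]:
    out = cfg.outdir
    counts = io_formats.read_matrix_tsv(_require(out / "mirna_counts.tsv", "mirna"))
    counts = counts.astype(int)
    mirna_genes = io_formats.read_bed(_require(out / "mirna_genes.bed", "mirna"))
    groups = _read_groups(out, "mirna")
    samples, _ = _load_cohort(cfg, "mirna")
    de = mirna_mod.test_demir(counts, groups)
    dp = out / "demir.tsv"
    de.to_csv(dp, sep="\t", float_format="%.6g")
    demirs = sorted(de.index[de["is_demir"]])
    cpm = mirna_mod.normalize_mirna(counts)
    cm = mirna_mod.correlate_cpg_mirna(
        samples, cpm, demirs, mirna_genes, n_perm=cfg.n_perm, seed=cfg.seed
    )
    cp = out / "cpg_mirna_pairs.tsv"
    cm.to_csv(cp, sep="\t", index=False, float_format="%.6g")
    written = [dp, cp]
    pred_path = out / "predicted_pairs.tsv"
    if pred_path.exists():
        expr = io_formats.read_matrix_tsv(_require(out / "expression.tsv", "mirna"))
        pred = pd.read_csv(pred_path, sep="\t")
        tgt = mirna_mod.correlate_mirna_targets(
            cpm, expr, list(pred.itertuples(index=False, name=None)),
            demirs=demirs, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        tp = out / "mirna_target_pairs.tsv"
        tgt.to_csv(tp, sep="\t", index=False, float_format="%.6g")
        written.append(tp)
    return written


def stage_variants(cfg: PipelineConfig) -> list[Path]:
    out = cfg.outdir
    var_tab = pd.read_csv(_require(out / "variants.tsv", "variants"), sep="\t")
    mu_tab = pd.read_csv(_require(out / "mutation_mu.tsv", "variants"), sep="\t")
    groups = _read_groups(out, "variants")
    selected = variants.select_candidate_genes(var_tab, groups)
    excess = variants.test_gene_set_excess(var_tab, mu_tab, groups, genes=selected)
    ep = out / "variant_excess.tsv"
    excess.to_csv(ep, sep="\t", float_format="%.6g")
    written = [ep]
    genes_path = out / "genes.bed12"
    if genes_path.exists() and selected:
        gene_models = io_formats.read_gene_models(genes_path)
        samples, _ = _load_cohort(cfg, "variants")
        indep = variants.methylation_independence_check(
            selected, var_tab, samples, gene_models, n_perm=cfg.n_perm, seed=cfg.seed
        )
        ip = out / "variant_methylation_independence.tsv"
        indep.to_csv(ip, sep="\t", index=False, float_format="%.6g")
        written.append(ip)
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "specific-lmrs": stage_specific_lmrs,
    "site-stats": stage_site_stats,
    "gsea": stage_gsea,
    "mirna": stage_mirna,
    "variants": stage_variants,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | None = None
) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    todo = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            "cohort": dataclasses.asdict(cfg.cohort),
            "window_cpgs": cfg.window_cpgs,
            "fdr_bound": cfg.fdr_bound,
            "min_cov": cfg.min_cov,
            "n_perm": cfg.n_perm,
            "kmeans_k": cfg.kmeans_k,
        },
        "stages": {},
    }
    for stage in todo:
        outputs = _STAGE_FUNCS[stage](cfg)
        manifest["stages"][stage] = {
            str(p.name): _sha256(p) for p in sorted(outputs)
        }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
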
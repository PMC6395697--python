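"""Disease-specific LMR calling, profiling, clustering and annotation.

A consensus LMR is the single-linkage union (>= 1 bp overlap) of
per-sample LMR calls.  A consensus region counts as *detected* in a
sample when at least one base of that sample's LMRs overlaps it, and it
is *group-specific* when detected in more than two samples of one group
and in no sample of the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from .types import (
    GeneModel,
    GenomicInterval,
    MethylomeSample,
    Segment,
    merge_intervals,
    total_bp,
    total_overlap_bp,
)


@dataclass
class SpecificRegionSet:
    """Consensus LMRs specific to one disease group."""

    group: str
    regions: list[GenomicInterval]
    support: pd.DataFrame  # columns n_ra_detected, n_oa_detected per region
    profile_cluster: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.regions)


def _segments_to_intervals(segments: list[Segment]) -> list[GenomicInterval]:
    return [s.interval if isinstance(s, Segment) else s for s in segments]


def call_group_specific_lmrs(
    lmrs_by_sample: dict[str, list[Segment]],
    groups: dict[str, str],
    min_support: int = 3,
) -> tuple[SpecificRegionSet, SpecificRegionSet]:
    """Call RA- and OA-specific consensus LMRs.

    ``min_support`` is the minimum number of detecting samples in the
    target group (default 3, i.e. "more than two"); the other group must
    contribute zero detections.
    """
    ra_ids = [s for s in lmrs_by_sample if groups.get(s) == "RA"]
    oa_ids = [s for s in lmrs_by_sample if groups.get(s) == "OA"]
    if not ra_ids or not oa_ids:
        raise ValueError("need at least one sample per group")

    all_ivs = [
        iv
        for sid in lmrs_by_sample
        for iv in _segments_to_intervals(lmrs_by_sample[sid])
    ]
    consensus = merge_intervals(all_ivs) if all_ivs else []

    n_ra = np.zeros(len(consensus), dtype=int)
    n_oa = np.zeros(len(consensus), dtype=int)
    for sid, segs in lmrs_by_sample.items():
        ivs = merge_intervals(_segments_to_intervals(segs)) if segs else []
        for ci, c in enumerate(consensus):
            if any(c.overlaps(iv) for iv in ivs):
                if groups[sid] == "RA":
                    n_ra[ci] += 1
                else:
                    n_oa[ci] += 1

    def build(group: str) -> SpecificRegionSet:
        own, other = (n_ra, n_oa) if group == "RA" else (n_oa, n_ra)
        keep = [
            ci
            for ci in range(len(consensus))
            if own[ci] >= min_support and other[ci] == 0
        ]
        support = pd.DataFrame(
            {
                "n_ra_detected": n_ra[keep],
                "n_oa_detected": n_oa[keep],
            },
            index=[f"{group}_LMR_{i:04d}" for i in range(len(keep))],
        )
        regions = [
            GenomicInterval(
                consensus[ci].chrom,
                consensus[ci].start,
                consensus[ci].end,
                name=f"{group}_LMR_{i:04d}",
            )
            for i, ci in enumerate(keep)
        ]
        return SpecificRegionSet(group, regions, support)

    return build("RA"), build("OA")


@dataclass
class ProfileMatrix:
    """Mean methylation in positional bins around specific-LMR centers."""

    region_ids: list[str]
    bin_edges: np.ndarray  # relative to region center
    values: np.ndarray  # rows = regions, cols = group-concatenated bins
    column_groups: list[str]


def profile_and_cluster_lmrs(
    region_set: SpecificRegionSet,
    samples: list[MethylomeSample],
    k: int = 2,
    flank: int = 1500,
    bin_width: int = 100,
    seed: int = 0,
) -> tuple[ProfileMatrix, np.ndarray]:
    """Profile methylation around region centers and k-means cluster rows.

    Per region, mean beta is computed in ``bin_width``-bp bins spanning
    center +/- ``flank`` for each group (bins of all group's samples
    pooled); k-means (50 seeded restarts, best inertia kept) clusters the
    group-concatenated row profiles.  Rows whose profile is entirely
    missing are dropped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not region_set.regions:
        raise ValueError("empty region set")
    n_bins = 2 * flank // bin_width
    edges = np.arange(-flank, flank + 1, bin_width)
    group_order = ["RA", "OA"]

    rows = []
    for region in region_set.regions:
        center = region.midpoint
        prof = np.full(2 * n_bins, np.nan)
        for gi, g in enumerate(group_order):
            sums = np.zeros(n_bins)
            cnts = np.zeros(n_bins)
            for s in (x for x in samples if x.group == g):
                on = s.chrom == region.chrom
                rel = s.pos[on] - center
                sel = (rel >= -flank) & (rel < flank)
                if not sel.any():
                    continue
                b = np.clip(((rel[sel] + flank) // bin_width).astype(int), 0, n_bins - 1)
                beta = s.beta[on][sel]
                good = ~np.isnan(beta)
                np.add.at(sums, b[good], beta[good])
                np.add.at(cnts, b[good], 1)
            with np.errstate(invalid="ignore"):
                prof[gi * n_bins : (gi + 1) * n_bins] = np.where(
                    cnts > 0, sums / np.maximum(cnts, 1), np.nan
                )
        rows.append(prof)
    values = np.array(rows)

    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropped {int(all_missing.sum())} regions with all-missing profiles",
            stacklevel=2,
        )
    keep = ~all_missing
    values = values[keep]
    region_ids = [r.name or f"region_{i}" for i, r in enumerate(region_set.regions)]
    region_ids = [rid for rid, k_ in zip(region_ids, keep) if k_]

    matrix = ProfileMatrix(
        region_ids,
        edges,
        values,
        [g for g in group_order for _ in range(n_bins)],
    )
    # impute residual missing bins with the row mean for clustering only
    X = values.copy()
    row_means = np.nanmean(X, axis=1)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = row_means[nan_r]

    if k == 1 or len(X) <= 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        km = KMeans(n_clusters=min(k, len(X)), n_init=50, random_state=seed)
        labels = km.fit_predict(X)
    region_set.profile_cluster = labels
    return matrix, labels


def jaccard_sample_clustering(
    lmrs_by_sample: dict[str, list[Segment]],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise base-pair Jaccard of sample LMR sets + average-linkage tree.

    Jaccard(a, b) = shared bp / union bp of the two merged LMR sets.
    A sample with zero LMR bases has Jaccard 0 with any non-empty set;
    two empty sets get 1 by convention (with a warning).  Returns the
    symmetric Jaccard matrix and a scipy linkage on distance 1 - J.
    """
    sids = list(lmrs_by_sample)
    if len(sids) < 2:
        raise ValueError("need at least 2 samples")
    ivs = {
        sid: merge_intervals(_segments_to_intervals(lmrs_by_sample[sid]))
        if lmrs_by_sample[sid]
        else []
        for sid in sids
    }
    bp = {sid: total_bp(ivs[sid]) for sid in sids}
    n = len(sids)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sids[i], sids[j]
            if bp[a] == 0 and bp[b] == 0:
                warnings.warn(
                    f"samples {a} and {b} both have empty LMR sets; Jaccard = 1",
                    stacklevel=2,
                )
                jac = 1.0
            elif bp[a] == 0 or bp[b] == 0:
                jac = 0.0
            else:
                inter = total_overlap_bp(ivs[a], ivs[b])
                jac = inter / (bp[a] + bp[b] - inter)
            J[i, j] = J[j, i] = jac
    matrix = pd.DataFrame(J, index=sids, columns=sids)
    dist = squareform(1.0 - J, checks=False)
    linkage = hierarchy.linkage(dist, method="average")
    return matrix, linkage


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def render_full(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        parts = []
        for child in (node.get_left(), node.get_right()):
            sub = render_full(child)
            parts.append(f"{sub}:{max(node.dist - child.dist, 0):.6g}")
        return "(" + ",".join(parts) + ")"

    return render_full(tree) + ";"


@dataclass(frozen=True)
class AnnotationRecord:
    region: GenomicInterval
    category: str  # promoter | exon | intron | intergenic
    gene: str | None
    intron_index: int | None  # 1-based from the 5' end, intronic only
    relative_position: float | None  # (midpoint - TSS)/length, clipped [0,1]


def annotate_lmr_position(
    regions: list[GenomicInterval],
    gene_models: list[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
) -> list[AnnotationRecord]:
    """Annotate each region midpoint against gene models.

    Category precedence: promoter > exon > intron > intergenic.  The
    promoter is TSS -1000/+100 bp, strand-aware.  Intron indices count
    5' -> 3' on the transcript strand; ``relative_position`` is the
    strand-aware fractional position of the midpoint along the
    transcript.
    """
    known_chroms = {g.chrom for g in gene_models}
    rank = {"promoter": 0, "exon": 1, "intron": 2}
    out: list[AnnotationRecord] = []
    for region in regions:
        if region.chrom not in known_chroms:
            warnings.warn(
                f"region chromosome {region.chrom!r} absent from gene models; "
                "annotated intergenic",
                stacklevel=2,
            )
            out.append(AnnotationRecord(region, "intergenic", None, None, None))
            continue
        mid = region.midpoint
        best: AnnotationRecord | None = None
        for g in gene_models:
            if g.chrom != region.chrom:
                continue
            cat, intron_idx = None, None
            if g.strand == "+":
                prom = (g.tss - promoter_upstream, g.tss + promoter_downstream)
            else:
                prom = (g.tss - promoter_downstream + 1, g.tss + promoter_upstream + 1)
            if prom[0] <= mid < prom[1]:
                cat = "promoter"
            elif g.interval.start <= mid < g.interval.end:
                introns = g.introns()
                in_intron = None
                for ii, (s, e) in enumerate(introns):
                    if s <= mid < e:
                        in_intron = ii
                        break
                if in_intron is None:
                    cat = "exon"
                else:
                    cat = "intron"
                    if g.strand == "+":
                        intron_idx = in_intron + 1
                    else:
                        intron_idx = len(introns) - in_intron
            if cat is None:
                continue
            rel = (mid - g.tss) / g.interval.length
            if g.strand == "-":
                rel = -rel
            rel = float(np.clip(rel, 0.0, 1.0))
            rec = AnnotationRecord(region, cat, g.name, intron_idx, rel)
            if best is None or rank[cat] < rank[best.category]:
                best = rec
        out.append(best or AnnotationRecord(region, "intergenic", None, None, None))
    return out


def enhancer_overlap_ratio(
    ra_regions: list[GenomicInterval],
    oa_regions: list[GenomicInterval],
    enhancers_by_celltype: dict[str, list[GenomicInterval]],
) -> pd.DataFrame:
    """Per cell type: RA/OA enhancer-overlap fraction ratio + chi-squared p.

    ``p_RA`` is the fraction of RA-specific LMRs overlapping (>= 1 bp) any
    enhancer of the cell type, ``p_OA`` likewise; the ratio p_RA / p_OA is
    reported (+inf when p_OA = 0) with a 1-df Pearson chi-squared p value
    (no continuity correction) on the 2x2 overlap table.
    """
    if not ra_regions or not oa_regions:
        raise ValueError("both region sets must be non-empty")
    rows = []
    for celltype, enhancers in enhancers_by_celltype.items():
        merged = merge_intervals(enhancers) if enhancers else []

        def n_overlap(regs: list[GenomicInterval]) -> int:
            return sum(any(r.overlaps(e) for e in merged) for r in regs)

        ra_hit = n_overlap(ra_regions)
        oa_hit = n_overlap(oa_regions)
        p_ra = ra_hit / len(ra_regions)
        p_oa = oa_hit / len(oa_regions)
        ratio = np.inf if p_oa == 0 else p_ra / p_oa
        table = np.array(
            [
                [ra_hit, len(ra_regions) - ra_hit],
                [oa_hit, len(oa_regions) - oa_hit],
            ]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            p = 1.0  # degenerate margin: no information
        else:
            _, p, _, _ = chi2_contingency(table, correction=False)
        rows.append(
            {
                "celltype": celltype,
                "ra_overlap_fraction": p_ra,
                "oa_overlap_fraction": p_oa,
                "ratio": ratio,
                "chi2_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("celltype")
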
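"""Readers/writers for the genomic and tabular formats the pipeline touches.

Supported formats:

* Bismark coverage files (``chrom  start(1-based)  end  meth%  n_meth
  n_unmeth``), read into :class:`~methylscape.types.MethylomeSample`;
* BED3/BED6 interval files and BED12 gene models;
* TSV matrices (rows x samples) via pandas;
* bedGraph export of per-sample beta values.

All coordinates are converted to the package-wide 0-based half-open
convention on read.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    GeneModel,
    GenomicInterval,
    MethylomeSample,
    ParseError,
    Segment,
)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bismark_coverage(path, sample_id: str, group: str) -> MethylomeSample:
    """Read a Bismark coverage file into a sorted, deduplicated sample.

    Input columns: chrom, start (1-based), end, methylation %, count
    methylated, count unmethylated.  Positions are shifted to 0-based;
    coverage is ``meth + unmeth`` (the count columns win over the percent
    column, with a warning when they disagree by more than one unit).
    Duplicate (chrom, pos) records are collapsed by summing counts.
    """
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    covs: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if start < 1:
                raise ParseError(f"{path}: line {lineno}: position must be >= 1 (1-based)")
            cov = n_meth + n_unmeth
            if cov > 0 and abs(pct - 100.0 * n_meth / cov) > 1.0:
                warnings.warn(
                    f"{path}: line {lineno}: methylation% inconsistent with counts; counts win",
                    stacklevel=2,
                )
            chroms.append(chrom)
            poss.append(start - 1)
            meths.append(n_meth)
            covs.append(cov)

    if not poss:
        return MethylomeSample(
            sample_id, group,
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.array([], dtype=np.int64), np.array([], dtype=np.int64),
        )

    df = pd.DataFrame({"chrom": chroms, "pos": poss, "meth": meths, "cov": covs})
    df = (
        df.groupby(["chrom", "pos"], sort=False, as_index=False)[["meth", "cov"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
    )
    return MethylomeSample(
        sample_id, group,
        df["chrom"].to_numpy(), df["pos"].to_numpy(),
        df["cov"].to_numpy(), df["meth"].to_numpy(),
    )


def write_bismark_coverage(sample: MethylomeSample, path) -> None:
    """Inverse of :func:`read_bismark_coverage` (positions back to 1-based)."""
    with open(path, "wt") as fh:
        beta = sample.beta
        for i in range(len(sample)):
            pct = 0.0 if np.isnan(beta[i]) else 100.0 * beta[i]
            fh.write(
                f"{sample.chrom[i]}\t{sample.pos[i] + 1}\t{sample.pos[i] + 1}\t"
                f"{pct:.6g}\t{sample.meth[i]}\t{sample.cov[i] - sample.meth[i]}\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open), in file order."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name, strand))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(items: Iterable, path) -> None:
    """Write Segments or GenomicIntervals as BED; name column = class/name."""
    with open(path, "wt") as fh:
        for item in items:
            if isinstance(item, Segment):
                iv, name = item.interval, item.klass
            else:
                iv, name = item, item.name or "."
            cols = [iv.chrom, str(iv.start), str(iv.end), name]
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read BED12 gene models (blockCount/blockSizes/blockStarts)."""
    out: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: BED12 requires 12 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}: line {lineno}: block count mismatch")
            exon_starts = tuple(start + o for o in offsets)
            exon_ends = tuple(start + o + s for o, s in zip(offsets, sizes))
            try:
                out.append(
                    GeneModel(
                        GenomicInterval(chrom, start, end, name, strand),
                        exon_starts, exon_ends,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - iv.start) for s in g.exon_starts)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}"
                f"\t{iv.start}\t{iv.end}\t0\t{len(g.exon_starts)}\t{sizes}\t{offsets}\n"
            )


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a labeled numeric matrix (first column = row ids, header = samples).

    Non-numeric cells become NaN; duplicate row ids and ragged rows are
    errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids: {dupes[:5]}")
    return df.apply(pd.to_numeric, errors="coerce")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_bedgraph(sample: MethylomeSample, path) -> None:
    """Export per-CpG beta values as bedGraph."""
    beta = sample.beta
    with open(path, "wt") as fh:
        for i in range(len(sample)):
            if np.isnan(beta[i]):
                continue
            fh.write(f"{sample.chrom[i]}\t{sample.pos[i]}\t{sample.pos[i] + 1}\t{beta[i]:.4f}\n")
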
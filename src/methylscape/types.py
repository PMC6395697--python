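"""Core domain types shared across the pipeline.

Coordinate convention: everything in-memory is 0-based, half-open
``[start, end)``.  Bismark coverage files are 1-based on disk and are
shifted on read (see :mod:`methylscape.io_formats`).  Chromosome names are
taken verbatim; no ``chr`` prefix normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("RA", "OA")

SEGMENT_CLASSES = ("PMD", "UMR", "LMR")

#: UMR/LMR split: hypomethylated regions with at least this many CpGs are
#: UMRs (typically CpG-island promoters), smaller ones are LMRs (typically
#: distal regulatory elements).
UMR_MIN_CPGS = 30


class MethylscapeError(Exception):
    """Base class for package errors."""


class ParseError(MethylscapeError):
    """A malformed input file; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class MethylomeSample:
    """One subject's per-CpG methylation calls.

    Sites are stored as parallel numpy arrays sorted by (chrom, pos) with no
    duplicate positions.  ``beta`` is methylated reads / coverage.
    """

    sample_id: str
    group: str
    chrom: np.ndarray  # dtype str/object, one entry per CpG
    pos: np.ndarray  # int64, 0-based cytosine position
    cov: np.ndarray  # int64, >= 0
    meth: np.ndarray  # int64, 0 <= meth <= cov

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        n = len(self.pos)
        if not (len(self.chrom) == len(self.cov) == len(self.meth) == n):
            raise ValueError("site arrays have inconsistent lengths")
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cov = np.asarray(self.cov, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        if n:
            if self.pos.min() < 0:
                raise ValueError("negative CpG position")
            if (self.meth < 0).any() or (self.meth > self.cov).any():
                raise ValueError("need 0 <= meth <= cov at every site")
            # verify sorted, deduplicated within chromosome blocks
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (np.diff(self.pos) <= 0)):
                raise ValueError("sites must be sorted with unique positions")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def beta(self) -> np.ndarray:
        """Methylation level per site; NaN where coverage is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.cov > 0, self.meth / np.maximum(self.cov, 1), np.nan)

    def subset(self, mask: np.ndarray) -> "MethylomeSample":
        return MethylomeSample(
            self.sample_id,
            self.group,
            self.chrom[mask],
            self.pos[mask],
            self.cov[mask],
            self.meth[mask],
        )


@dataclass(frozen=True)
class Segment:
    """A classified methylome segment (PMD, UMR or LMR)."""

    interval: GenomicInterval
    klass: str
    n_cpg: int
    mean_meth: float

    def __post_init__(self) -> None:
        if self.klass not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.klass!r}")
        if self.n_cpg < 1:
            raise ValueError("segment must contain at least one CpG")
        if self.klass == "UMR" and self.n_cpg < UMR_MIN_CPGS:
            raise ValueError(f"UMR requires >= {UMR_MIN_CPGS} CpGs")
        if self.klass == "LMR" and self.n_cpg >= UMR_MIN_CPGS:
            raise ValueError(f"LMR requires < {UMR_MIN_CPGS} CpGs")
        if not (0.0 <= self.mean_meth <= 1.0) and not np.isnan(self.mean_meth):
            raise ValueError("mean_meth outside [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with exon blocks, BED12-style.

    ``tss`` is strand-aware: the interval start for ``+`` genes and
    ``end - 1`` for ``-`` genes.
    """

    interval: GenomicInterval
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene model requires explicit strand")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError("exon block lists must be non-empty and matched")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError("empty exon block")
            if s < self.interval.start or e > self.interval.end:
                raise ValueError("exon block outside transcript interval")
            if prev_end is not None and s < prev_end:
                raise ValueError("exon blocks overlap or are unsorted")
            prev_end = e

    @property
    def name(self) -> str | None:
        return self.interval.name

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def n_introns(self) -> int:
        return len(self.exon_starts) - 1

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in genomic order (not strand order)."""
        return [
            (e, s)
            for e, s in zip(self.exon_ends[:-1], self.exon_starts[1:])
            if s > e
        ]


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals by single-linkage on >= 1 bp overlap.

    Abutting intervals (end == start) are NOT merged: merging requires a
    shared base.
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:  # >=1 bp overlap
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def total_overlap_bp(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> int:
    """Total base pairs shared between two interval sets (merged first)."""
    a_m, b_m = merge_intervals(a) if a else [], merge_intervals(b) if b else []
    total = 0
    for chrom in {iv.chrom for iv in a_m} & {iv.chrom for iv in b_m}:
        xs = [iv for iv in a_m if iv.chrom == chrom]
        ys = [iv for iv in b_m if iv.chrom == chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if hi > lo:
                total += hi - lo
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return total


def total_bp(intervals: list[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0
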
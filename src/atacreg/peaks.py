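"""Consensus peak construction and filtering.

Per-sample ATAC-seq peak calls (scored intervals) are reduced to a single
consensus peak set: peaks passing a q-value cutoff in each sample are pooled
and merged, then the merged set is filtered on read support, a CPM ceiling,
blacklist overlap and autosomal location.  All coordinates are 0-based
half-open, the BED convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: chromosomes retained by the autosome filter ("chr" prefix dialect)
DEFAULT_AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
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

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class ScoredPeak:
    """A called peak with its q-value and (optionally) a summit offset from start."""

    interval: GenomicInterval
    q: float
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.q <= 1.0):
            raise ValueError(f"q-value must be in (0, 1], got {self.q}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset must lie within the peak")

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when no summit was called."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


class CountsMatrix:
    """Integer feature x sample count matrix with per-sample library sizes.

    ``lib_sizes`` are the per-sample sequencing totals used for CPM
    normalization.  When not given they default to the column sums (all
    counted reads fall in features); real ATAC libraries have most reads
    outside peaks, so callers should pass the true totals where known.
    """

    def __init__(
        self,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
        values,
        lib_sizes=None,
    ) -> None:
        values = np.asarray(values)
        if values.ndim != 2 or values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)
        self.values = values.astype(np.int64, copy=False)
        if lib_sizes is None:
            lib_sizes = self.values.sum(axis=0).astype(float)
        lib_sizes = np.asarray(lib_sizes, dtype=float)
        if lib_sizes.shape != (len(self.sample_ids),):
            raise ValueError("lib_sizes length must match sample count")
        self.lib_sizes = lib_sizes
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        try:
            return self.values[self._index[feature_id]]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not present in counts matrix")

    def subset_features(self, feature_ids: Sequence[str]) -> "CountsMatrix":
        missing = [f for f in feature_ids if f not in self._index]
        if missing:
            raise KeyError(f"features missing from counts matrix: {missing[:5]}")
        rows = [self._index[f] for f in feature_ids]
        return CountsMatrix(
            feature_ids, self.sample_ids, self.values[rows], self.lib_sizes
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountsMatrix":
        cols = [self.sample_ids.index(s) for s in sample_ids]
        return CountsMatrix(
            self.feature_ids, sample_ids, self.values[:, cols], self.lib_sizes[cols]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lib_sizes=None) -> "CountsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(), lib_sizes)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals into a sorted, disjoint set."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_consensus(
    peak_sets: Sequence[Sequence[ScoredPeak]], q_max: float = 0.01
) -> list[GenomicInterval]:
    """Merge per-sample peak calls passing the q-value cutoff into a consensus set.

    Peaks with q <= ``q_max`` (1% by default) from every sample are pooled and
    their union merged; overlapping or book-ended intervals coalesce.  Returns
    a sorted, non-overlapping interval list.  An empty surviving set yields an
    empty result with a warning.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    surviving = [
        p.interval for peaks in peak_sets for p in peaks if p.q <= q_max
    ]
    if not surviving:
        warnings.warn(
            f"no peaks pass q <= {q_max}; consensus set is empty", stacklevel=2
        )
        return []
    return merge_intervals(surviving)


def assign_peak_ids(
    intervals: Sequence[GenomicInterval], prefix: str = "peak"
) -> list[GenomicInterval]:
    """Name intervals ``peak_000001`` ... in their given order."""
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{prefix}_{i + 1:06d}")
        for i, iv in enumerate(intervals)
    ]


def compute_cpm(counts: CountsMatrix) -> np.ndarray:
    """Counts-per-million: cpm[i, j] = counts[i, j] * 1e6 / lib_sizes[j]."""
    if np.any(counts.lib_sizes <= 0):
        raise ValueError("library sizes must be positive for CPM normalization")
    return counts.values * 1e6 / counts.lib_sizes[np.newaxis, :]


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def filter_consensus(
    peaks: Sequence[GenomicInterval],
    counts: CountsMatrix,
    blacklist: Sequence[GenomicInterval] = (),
    min_reads: int = 20,
    max_cpm: float = 500.0,
    autosomes: frozenset[str] | set[str] = DEFAULT_AUTOSOMES,
) -> list[GenomicInterval]:
    """Filter consensus peaks on support, CPM ceiling, blacklist and autosomes.

    A peak survives iff

    * max over samples of its raw count is strictly greater than ``min_reads``
      (likely-false-positive filter),
    * max over samples of its CPM does not exceed ``max_cpm`` (artifact
      filter, inclusive bound),
    * it overlaps no blacklisted region (>= 1 bp overlap excludes), and
    * its chromosome is autosomal.

    Peaks must be named and every name must have a counts row; a missing row
    raises ``KeyError`` naming the peak.  Input order is preserved.
    """
    cpm = compute_cpm(counts)
    cpm_by_feature = dict(zip(counts.feature_ids, cpm.max(axis=1)))
    max_by_feature = dict(zip(counts.feature_ids, counts.values.max(axis=1)))
    black_trees = _build_trees(blacklist)

    kept: list[GenomicInterval] = []
    for peak in peaks:
        if peak.name is None or peak.name not in max_by_feature:
            raise KeyError(f"no counts row for peak {peak.name or peak!r}")
        if max_by_feature[peak.name] <= min_reads:
            continue
        if cpm_by_feature[peak.name] > max_cpm:
            continue
        tree = black_trees.get(peak.chrom)
        if tree is not None and tree.overlap(peak.start, peak.end):
            continue
        if peak.chrom not in autosomes:
            continue
        kept.append(peak)
    return kept
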
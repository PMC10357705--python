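"""Exact set arithmetic on genomic intervals.

Every base-pair statistic in the pipeline (locus dark overlap, gene-body and
CDS dark fractions) reduces to operations on :class:`IntervalSet`, a
per-chromosome sorted, merged collection of 0-based half-open intervals.
Algorithms are sort + linear sweep; all queries here are batch, so no
interval tree is needed. Strand is ignored throughout: dark regions are
mappability artifacts and carry no strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "normalize",
    "intersect",
    "intersect_length",
    "count_source_overlaps",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test: abutting intervals do NOT overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class IntervalSet:
    """Per-chromosome sorted, disjoint, merged intervals.

    Internally stored as ``(n, 2)`` int64 arrays per chromosome. Consecutive
    intervals are separated by at least one base (book-ended inputs are
    merged: coverage semantics).
    """

    _chroms: Dict[str, np.ndarray] = field(default_factory=dict)

    @staticmethod
    def from_intervals(intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: Dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            arr = np.asarray(sorted(spans), dtype=np.int64)
            merged[chrom] = _sweep_merge(arr)
        return IntervalSet(merged)

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str) -> np.ndarray:
        """The ``(n, 2)`` array for one chromosome (empty if absent)."""
        return self._chroms.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._chroms.values())
        )

    def __len__(self) -> int:
        return int(sum(arr.shape[0] for arr in self._chroms.values()))

    def __bool__(self) -> bool:
        return len(self) > 0

    def to_intervals(self) -> List[GenomicInterval]:
        out: List[GenomicInterval] = []
        for chrom in self.chromosomes:
            for start, end in self._chroms[chrom]:
                out.append(GenomicInterval(chrom, int(start), int(end)))
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        result: Dict[str, np.ndarray] = {}
        for chrom in self._chroms:
            if chrom not in other._chroms:
                continue
            arr = _intersect_arrays(self._chroms[chrom], other._chroms[chrom])
            if arr.shape[0]:
                result[chrom] = arr
        return IntervalSet(result)

    def intersect_length(self, other: "IntervalSet") -> int:
        total = 0
        for chrom in self._chroms:
            if chrom not in other._chroms:
                continue
            arr = _intersect_arrays(self._chroms[chrom], other._chroms[chrom])
            total += int((arr[:, 1] - arr[:, 0]).sum())
        return total


def _sweep_merge(sorted_spans: np.ndarray) -> np.ndarray:
    """Merge sorted (start, end) spans; book-ended spans coalesce."""
    if sorted_spans.shape[0] == 0:
        return sorted_spans.reshape(0, 2)
    merged = [list(sorted_spans[0])]
    for start, end in sorted_spans[1:]:
        if start <= merged[-1][1]:  # overlap or touch
            if end > merged[-1][1]:
                merged[-1][1] = end
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-pointer sweep over two merged, sorted span arrays."""
    out: List[Tuple[int, int]] = []
    i = j = 0
    na, nb = a.shape[0], b.shape[0]
    while i < na and j < nb:
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def normalize(intervals: Iterable[GenomicInterval]) -> IntervalSet:
    """Sort by (chrom, start) and sweep-merge into an :class:`IntervalSet`."""
    return IntervalSet.from_intervals(intervals)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    return a.intersect_length(b)


def count_source_overlaps(
    source: Iterable[GenomicInterval], query: GenomicInterval
) -> int:
    """Number of *unmerged* source records overlapping ``query`` by >= 1 bp.

    Record counts, not merged-run counts: two abutting dark records that each
    overlap a locus count as 2. Half-open semantics, so a record ending
    exactly at ``query.start`` does not overlap.
    """
    return sum(1 for rec in source if rec.overlaps(query))
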
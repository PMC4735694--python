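"""Genomic interval arithmetic for callable-region bookkeeping.

All intervals are 0-based, half-open (BED convention), strand-less.  VCF
positions (1-based) are converted at the boundary by subtracting one.  The
operations here are the denominator side of mutation-rate estimation:
subtracting no-call/repeat masks from a genome extent, intersecting per-member
callable tracks, and splitting effective bases into CpG / non-CpG partitions.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np


class IntervalSet:
    """Per-chromosome sorted, merged, non-overlapping half-open intervals.

    Parameters
    ----------
    intervals
        Mapping of chromosome name to an iterable of ``(start, end)`` pairs,
        or an iterable of ``(chrom, start, end)`` triples.  Inputs may overlap
        or be unsorted; they are normalized (sorted and merged) on
        construction.  Zero- or negative-length intervals are dropped.
    """

    def __init__(self, intervals=None):
        self._chroms: dict[str, np.ndarray] = {}
        if intervals is None:
            return
        if isinstance(intervals, Mapping):
            items = ((c, s, e) for c, pairs in intervals.items() for s, e in pairs)
        else:
            items = intervals
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in items:
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        for chrom, pairs in by_chrom.items():
            arr = _merge(np.asarray(pairs, dtype=np.int64).reshape(-1, 2))
            if len(arr):
                self._chroms[chrom] = arr

    # -- basic accessors ----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def arrays(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) for one chromosome (possibly empty)."""
        return self._chroms.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(a) for a in self._chroms.values())

    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._chroms.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._chroms) != set(other._chroms):
            return False
        return all(np.array_equal(self._chroms[c], other._chroms[c]) for c in self._chroms)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_length()} bp)"

    def to_records(self) -> list[tuple[str, int, int]]:
        return [(c, int(s), int(e)) for c in self.chroms for s, e in self._chroms[c]]

    # -- membership ---------------------------------------------------------

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorized membership test for 0-based positions."""
        pos = np.asarray(positions, dtype=np.int64)
        arr = self.arrays(chrom)
        if not len(arr):
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < arr[idx[ok], 1]
        return out

    # -- set algebra ----------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self.to_records() + other.to_records())

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom in set(self._chroms) & set(other._chroms):
            arr = _intersect_arrays(self.arrays(chrom), other.arrays(chrom))
            if len(arr):
                out._chroms[chrom] = arr
        return out

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Set difference self \\ other (bedtools subtract semantics)."""
        out = IntervalSet()
        for chrom, arr in self._chroms.items():
            res = _subtract_arrays(arr, other.arrays(chrom))
            if len(res):
                out._chroms[chrom] = res
        return out

    # -- I/O ------------------------------------------------------------

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                recs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(recs)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.to_records():
                fh.write(f"{chrom}\t{start}\t{end}\n")


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge touching/overlapping intervals; drop empty ones."""
    arr = arr[arr[:, 1] > arr[:, 0]]
    if len(arr) <= 1:
        return arr.copy()
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    starts, ends = arr[:, 0], arr[:, 1]
    # an interval starts a new merged block when it begins after the running max end
    run_max = np.maximum.accumulate(ends)
    new_block = np.ones(len(arr), dtype=bool)
    new_block[1:] = starts[1:] > run_max[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    out = np.empty((n_blocks, 2), dtype=np.int64)
    out[:, 0] = starts[new_block]
    out[:, 1] = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    return out


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if not len(a) or not len(b):
        return np.empty((0, 2), dtype=np.int64)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if not len(a):
        return a.copy()
    if not len(b):
        return a.copy()
    out = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < end:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            if cur >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Functional alias for :meth:`IntervalSet.subtract`."""
    return a.subtract(b)


def trio_intersection(father: IntervalSet, mother: IntervalSet, child: IntervalSet) -> IntervalSet:
    """Callable bases shared by all three family members."""
    return father.intersect(mother).intersect(child)


def common_callable(
    nocall_masks: Iterable[IntervalSet],
    extent: IntervalSet,
    max_nocall_fraction: float = 0.01,
) -> IntervalSet:
    """Commonly callable region across a panel of individuals.

    A base is dropped when it is no-called in *at least*
    ``max_nocall_fraction`` of the individuals, i.e. when the no-call count is
    >= ceil(f * n).  The result is the complement of those bases within
    ``extent``.
    """
    masks = list(nocall_masks)
    n = len(masks)
    if n < 1:
        raise ValueError("common_callable requires at least one individual")
    if not (0 < max_nocall_fraction <= 1):
        raise ValueError("max_nocall_fraction must be in (0, 1]")
    threshold = max(1, math.ceil(max_nocall_fraction * n))
    bad = _coverage_at_least(masks, threshold)
    return extent.subtract(bad)


def _coverage_at_least(masks: list[IntervalSet], k: int) -> IntervalSet:
    """Sweep-line: positions covered by >= k of the given interval sets."""
    chroms = set()
    for m in masks:
        chroms.update(m.chroms)
    out = IntervalSet()
    for chrom in chroms:
        events = []
        for m in masks:
            arr = m.arrays(chrom)
            if len(arr):
                events.append(np.stack([arr[:, 0], np.ones(len(arr), dtype=np.int64)], axis=1))
                events.append(np.stack([arr[:, 1], -np.ones(len(arr), dtype=np.int64)], axis=1))
        if not events:
            continue
        ev = np.concatenate(events)
        order = np.lexsort((ev[:, 1], ev[:, 0]))
        ev = ev[order]
        pos, delta = ev[:, 0], ev[:, 1]
        # collapse duplicate positions
        uniq, inv = np.unique(pos, return_inverse=True)
        dsum = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(dsum, inv, delta)
        cov = np.cumsum(dsum)
        above = cov >= k
        recs = []
        for i in np.flatnonzero(above):
            if i + 1 < len(uniq):
                recs.append((uniq[i], uniq[i + 1]))
        if recs:
            arr = _merge(np.asarray(recs, dtype=np.int64))
            if len(arr):
                out._chroms[chrom] = arr
    return out


def partition_cpg(effective: IntervalSet, cpg_sites: IntervalSet) -> tuple[int, int]:
    """Split effective bases into (cpg_bases, noncpg_bases).

    ``cpg_sites`` should mark both the C and the G of each CpG dinucleotide
    on the forward strand.
    """
    cpg = effective.intersect(cpg_sites).total_length()
    return cpg, effective.total_length() - cpg
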
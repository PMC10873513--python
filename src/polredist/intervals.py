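"""Shared interval arithmetic: merging, overlap queries, read-to-region indexing.

These helpers back the exon/blacklist filters and the three gene-counting
modes. Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "MergedIntervalSet", "RegionIndex"]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals as a sorted disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


class MergedIntervalSet:
    """Per-chromosome disjoint interval union supporting vectorized any-overlap tests."""

    def __init__(self, intervals_by_chrom: dict[str, list[tuple[int, int]]]) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals_by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.asarray([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.asarray([e for _, e in merged], dtype=np.int64)

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: does [starts[i], ends[i]) intersect any stored interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        ivs = self._starts.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.zeros(len(starts), dtype=bool)
        # candidate: last interval starting before the query end
        idx = np.searchsorted(ivs, ends, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(starts), dtype=bool)
        hit[ok] = self._ends[chrom][idx[ok]] > starts[ok]
        return hit


class RegionIndex:
    """Maps query intervals to the labelled regions they overlap.

    Built from labelled (chrom, start, end, label) regions that may overlap
    one another; queries return, per read, the set of distinct labels hit.
    Internally a breakpoint decomposition: the genome is cut at every region
    boundary and each elementary segment stores its label set, so a query is
    one or two ``searchsorted`` lookups for typical short reads.
    """

    def __init__(self, regions: list[tuple[str, int, int, object]]) -> None:
        self._bounds: dict[str, np.ndarray] = {}
        self._labels: dict[str, list[tuple]] = {}
        by_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, s, e, lab in regions:
            by_chrom.setdefault(chrom, []).append((s, e, lab))
        for chrom, regs in by_chrom.items():
            pts = sorted({p for s, e, _ in regs for p in (s, e)})
            bounds = np.asarray(pts, dtype=np.int64)
            seg_labels: list[set] = [set() for _ in range(len(bounds) - 1)]
            for s, e, lab in regs:
                i0 = int(np.searchsorted(bounds, s, side="right")) - 1
                i1 = int(np.searchsorted(bounds, e, side="left"))
                for i in range(i0, i1):
                    seg_labels[i].add(lab)
            self._bounds[chrom] = bounds
            self._labels[chrom] = [tuple(sorted(x, key=repr)) for x in seg_labels]

    def query(self, chrom: str, start: int, end: int) -> tuple:
        """Distinct labels of regions overlapping [start, end)."""
        bounds = self._bounds.get(chrom)
        if bounds is None or len(bounds) < 2:
            return ()
        i0 = int(np.searchsorted(bounds, start, side="right")) - 1
        i1 = int(np.searchsorted(bounds, end - 1, side="right")) - 1
        labels = self._labels[chrom]
        nseg = len(labels)
        out: set = set()
        for i in range(max(i0, 0), min(i1, nseg - 1) + 1):
            out.update(labels[i])
        return tuple(sorted(out, key=repr))

    def query_single_labels(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> list[tuple]:
        """Vectorized-ish batch query (loops only over multi-segment reads)."""
        bounds = self._bounds.get(chrom)
        n = len(starts)
        if bounds is None or len(bounds) < 2:
            return [()] * n
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        i0 = np.searchsorted(bounds, starts, side="right") - 1
        i1 = np.searchsorted(bounds, ends - 1, side="right") - 1
        labels = self._labels[chrom]
        nseg = len(labels)
        out: list[tuple] = [()] * n
        same = i0 == i1
        for j in np.nonzero(same)[0]:
            k = i0[j]
            if 0 <= k < nseg:
                out[int(j)] = labels[k]
        for j in np.nonzero(~same)[0]:
            out[int(j)] = self.query(chrom, int(starts[j]), int(ends[j]))
        return out
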
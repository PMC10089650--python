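"""Small interval utilities shared across modules.

All intervals are 0-based half-open ``[start, end)`` on a named chromosome.
These helpers work on plain ``(start, end)`` integer pairs; callers group by
chromosome themselves.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting intervals into a disjoint sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Union length (bp) of a set of possibly overlapping intervals."""
    return sum(e - s for s, e in merge(intervals))


def intersect_length(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> int:
    """Length of the intersection of two interval sets (each merged first)."""
    ma, mb = merge(a), merge(b)
    i = j = 0
    out = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if s < e:
            out += e - s
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    return out


def covered_bp(interval: tuple[int, int], others: Sequence[tuple[int, int]]) -> int:
    """bp of ``interval`` covered by the union of ``others``."""
    return intersect_length([interval], others)


def uncovered_runs(interval: tuple[int, int], others: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximal sub-intervals of ``interval`` not covered by ``others``."""
    s0, e0 = interval
    runs = []
    pos = s0
    for s, e in merge(others):
        if e <= s0 or s >= e0:
            continue
        s, e = max(s, s0), min(e, e0)
        if s > pos:
            runs.append((pos, s))
        pos = max(pos, e)
    if pos < e0:
        runs.append((pos, e0))
    return runs


class IntervalIndex:
    """Sorted disjoint intervals supporting vectorized containment and overlap tests."""

    def __init__(self, intervals: Iterable[tuple[int, int]], merged: bool = False):
        ivs = sorted(intervals) if not merged else list(intervals)
        self.starts = np.asarray([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.asarray([e for _, e in ivs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    def contains(self, start, end) -> np.ndarray:
        """True where [start, end) lies fully inside one stored interval.

        Requires the stored intervals to be disjoint and sorted.
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros(start.shape, dtype=bool)
        idx = np.searchsorted(self.starts, start, side="right") - 1
        ok = idx >= 0
        idx = np.clip(idx, 0, len(self.starts) - 1)
        return ok & (end <= self.ends[idx]) & (start >= self.starts[idx])

    def overlaps(self, start, end) -> np.ndarray:
        """True where [start, end) overlaps any stored interval by >= 1 bp.

        Requires the stored intervals to be merged (disjoint, sorted).
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if len(self.starts) == 0:
            return np.zeros(start.shape, dtype=bool)
        # candidate: last interval starting before `end`
        idx = np.searchsorted(self.starts, end, side="left") - 1
        ok = idx >= 0
        idx = np.clip(idx, 0, len(self.starts) - 1)
        return ok & (self.ends[idx] > start)
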
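"""Vectorized arithmetic on disjoint, sorted genomic intervals.

All functions operate on per-chromosome ``(starts, ends)`` integer arrays
describing 0-based half-open intervals that are pairwise disjoint and sorted
by start. Building and querying these arrays is the hot path of every
coverage computation in the package.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(
    starts: np.ndarray, ends: np.ndarray, max_gap: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge intervals whose gap (next.start - prev.end) is <= max_gap.

    Input need not be disjoint but is sorted internally. Returns
    ``(merged_starts, merged_ends, group_index)`` where ``group_index[i]``
    is the output interval each input interval was merged into (aligned to
    the start-sorted input order).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends, np.empty(0, dtype=np.int64)
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    # running max of ends defines the frontier of the current chain
    run_end = np.maximum.accumulate(e)
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] - run_end[:-1] > max_gap
    group = np.cumsum(new_group) - 1
    n_groups = group[-1] + 1
    out_starts = s[new_group]
    out_ends = np.zeros(n_groups, dtype=np.int64)
    np.maximum.at(out_ends, group, e)
    return out_starts, out_ends, group


class IntervalSet:
    """Disjoint sorted intervals on one chromosome with O(log n) coverage queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray, *, merge: bool = True):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if merge and starts.size:
            starts, ends, _ = merge_intervals(starts, ends, max_gap=-1)
        self.starts = starts
        self.ends = ends
        lengths = ends - starts
        self._cum = np.concatenate(([0], np.cumsum(lengths)))

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def total_bp(self) -> int:
        return int(self._cum[-1])

    def _prefix(self, pos: np.ndarray) -> np.ndarray:
        """Covered bp strictly left of each position."""
        pos = np.asarray(pos, dtype=np.int64)
        j = np.searchsorted(self.starts, pos, side="right")
        covered = self._cum[j].astype(np.int64)
        inside = j > 0
        jm = np.maximum(j - 1, 0)
        # subtract the part of the previous interval at or right of pos
        overhang = np.clip(self.ends[jm] - pos, 0, self.ends[jm] - self.starts[jm])
        covered -= np.where(inside, overhang, 0)
        return covered

    def overlap_bp(self, qstarts, qends) -> np.ndarray:
        """Covered bp inside each query interval [qstart, qend)."""
        qstarts = np.atleast_1d(np.asarray(qstarts, dtype=np.int64))
        qends = np.atleast_1d(np.asarray(qends, dtype=np.int64))
        if len(self) == 0:
            return np.zeros(qstarts.shape, dtype=np.int64)
        return self._prefix(qends) - self._prefix(qstarts)

    def covers(self, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of single base positions."""
        positions = np.asarray(positions, dtype=np.int64)
        if len(self) == 0:
            return np.zeros(positions.shape, dtype=bool)
        j = np.searchsorted(self.starts, positions, side="right")
        inside = j > 0
        jm = np.maximum(j - 1, 0)
        return inside & (positions < self.ends[jm])
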
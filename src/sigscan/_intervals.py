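"""Small half-open interval helpers (numpy based, no external deps)."""

from __future__ import annotations

import numpy as np


def merge(starts, ends):
    """Merge overlapping/adjacent half-open intervals; returns sorted arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    new = np.concatenate(([True], s[1:] > cummax[:-1]))
    idx = np.flatnonzero(new)
    out_s = s[idx]
    out_e = np.maximum.reduceat(e, idx)
    # reduceat gives the max end within each group, which with the cummax
    # grouping is exactly the merged end
    out_e = np.maximum.accumulate(out_e)  # guard monotonicity
    return out_s, out_e


def total_length(starts, ends) -> int:
    s, e = merge(starts, ends)
    return int(np.sum(e - s))


def coverage(b_starts, b_ends, x0, x1):
    """Bases of the merged set B covered inside each query interval [x0, x1)."""
    x0 = np.asarray(x0, dtype=np.int64)
    x1 = np.asarray(x1, dtype=np.int64)
    if b_starts.size == 0:
        return np.zeros(x0.shape, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(b_ends - b_starts)))

    def cum_at(x):
        i = np.searchsorted(b_starts, x, side="right")
        base = cum[i]
        partial = np.where(
            (i > 0) & (x < b_ends[np.clip(i - 1, 0, None)]),
            b_ends[np.clip(i - 1, 0, None)] - x,
            0,
        )
        return base - partial

    return cum_at(x1) - cum_at(x0)


def intersection_length(a_starts, a_ends, b_starts, b_ends) -> int:
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    if a_s.size == 0 or b_s.size == 0:
        return 0
    return int(np.sum(coverage(b_s, b_e, a_s, a_e)))


def subtract(a_starts, a_ends, b_starts, b_ends):
    """A \\ B for interval sets; returns merged arrays."""
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    if a_s.size == 0 or b_s.size == 0:
        return a_s, a_e
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = int(s)
        while j < b_s.size and b_e[j] <= cur:
            j += 1
        k = j
        while k < b_s.size and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(cur)
                out_e.append(int(b_s[k]))
            cur = max(cur, int(b_e[k]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def point_lookup(starts, ends, positions):
    """Index of the (disjoint, sorted) interval containing each position, -1 if none."""
    positions = np.asarray(positions, dtype=np.int64)
    if starts.size == 0:
        return np.full(positions.shape, -1, dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    hit = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
    return np.where(hit, idx, -1)
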
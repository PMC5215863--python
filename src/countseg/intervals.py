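"""Sorted-interval arithmetic on numpy arrays.

All intervals are 0-based half-open [start, end). Functions operate on
per-chromosome (starts, ends) arrays; callers split by chromosome.
"""

from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping or touching intervals."""
    if len(starts) == 0:
        return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s = [s[0]]
    out_e = [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def total_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total covered nucleotides of a *merged* interval set."""
    return int(np.sum(np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64)))


def intersect_length(a_starts, a_ends, b_starts, b_ends) -> int:
    """Nucleotides in the intersection of two merged, sorted interval sets."""
    i = j = 0
    total = 0
    na, nb = len(a_starts), len(b_starts)
    while i < na and j < nb:
        lo = max(a_starts[i], b_starts[j])
        hi = min(a_ends[i], b_ends[j])
        if hi > lo:
            total += hi - lo
        if a_ends[i] < b_ends[j]:
            i += 1
        else:
            j += 1
    return int(total)


def overlaps_any(q_starts, q_ends, ref_starts, ref_ends,
                 min_overlap: int = 1) -> np.ndarray:
    """For each query interval, whether it overlaps the merged sorted
    reference by at least ``min_overlap`` bp. Vectorized over queries."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if len(ref_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    ref_starts = np.asarray(ref_starts, dtype=np.int64)
    ref_ends = np.asarray(ref_ends, dtype=np.int64)
    # candidate reference intervals: last ref starting before q_end and
    # first ref ending after q_start
    lo = np.searchsorted(ref_ends, q_starts, side="right")
    hi = np.searchsorted(ref_starts, q_ends, side="left")
    out = np.zeros(len(q_starts), dtype=bool)
    for k in range(len(q_starts)):
        best = 0
        for r in range(lo[k], hi[k]):
            ov = min(q_ends[k], ref_ends[r]) - max(q_starts[k], ref_starts[r])
            if ov > best:
                best = ov
        out[k] = best >= min_overlap
    return out


def points_in(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: point position lies inside a merged sorted interval set."""
    points = np.asarray(points, dtype=np.int64)
    if len(starts) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(np.asarray(starts, dtype=np.int64), points, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(points), dtype=bool)
    res[ok] = points[ok] < np.asarray(ends, dtype=np.int64)[idx[ok]]
    return res
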
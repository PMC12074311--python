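"""Dynamic time warping distance.

Classic dynamic-programming alignment with absolute-difference local cost and
an unconstrained warping window: symmetric, zero exactly for identical
series.  The inner loop is JIT-compiled (two-row table, O(len(a) * len(b))
time, O(len(b)) memory) because an explanation evaluates it hundreds of times
against series of ~1000 points.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dtw_distance"]


@njit(cache=True)
def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        curr[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = best + abs(a[i] - b[j])
        prev, curr = curr, prev
    return prev[m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Alignment cost between two 1-D series (raw values, no normalisation)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size == 0 or b.size == 0:
        raise ValueError("DTW requires two non-empty 1-D series")
    return float(_dtw_cost(a, b))
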
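"""Dynamic-programming kernels for dynamic time warping.

The accumulated-cost recursion is
``C[k, j] = d[k, j] + min(C[k-1, j], C[k-1, j-1], C[k, j-1])`` with
``C[0, 0] = d[0, 0]`` and boundary accumulation along the first row and
column. Kernels are numba-compiled; an optional Sakoe-Chiba band limits
``|k - j|``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = np.inf


@njit(cache=True)
def _local(a: float, b: float, metric: int) -> float:
    d = a - b
    if metric == 0:  # absolute difference
        return abs(d)
    return d * d  # squared difference


@njit(cache=True)
def accumulated_cost(x, y, metric, window):
    """Full (M, N) accumulated-cost matrix; window < 0 means unconstrained."""
    m, n = len(x), len(y)
    C = np.full((m, n), _INF)
    for k in range(m):
        lo, hi = 0, n
        if window >= 0:
            lo = max(0, k - window)
            hi = min(n, k + window + 1)
        for j in range(lo, hi):
            d = _local(x[k], y[j], metric)
            if k == 0 and j == 0:
                C[k, j] = d
            elif k == 0:
                C[k, j] = d + C[k, j - 1]
            elif j == 0:
                C[k, j] = d + C[k - 1, j]
            else:
                best = C[k - 1, j]
                if C[k - 1, j - 1] < best:
                    best = C[k - 1, j - 1]
                if C[k, j - 1] < best:
                    best = C[k, j - 1]
                C[k, j] = d + best
    return C


@njit(cache=True)
def all_pairs(X, metric, window):
    """Symmetric all-pairs DTW distance matrix for rows of X."""
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            C = accumulated_cost(X[i], X[j], metric, window)
            out[i, j] = C[-1, -1]
            out[j, i] = out[i, j]
    return out


def backtrack(C: np.ndarray) -> list[tuple[int, int]]:
    """Warping path (monotone, continuous) from an accumulated-cost matrix."""
    k, j = C.shape[0] - 1, C.shape[1] - 1
    path = [(k, j)]
    while k > 0 or j > 0:
        if k == 0:
            j -= 1
        elif j == 0:
            k -= 1
        else:
            candidates = ((C[k - 1, j - 1], k - 1, j - 1),
                          (C[k - 1, j], k - 1, j),
                          (C[k, j - 1], k, j - 1))
            _, k, j = min(candidates)
        path.append((k, j))
    path.reverse()
    return path
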
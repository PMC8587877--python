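"""Dynamic time warping with squared local costs.

The distance used throughout this package is the *sum of squared
differences along the optimal warping path*, with no final square root.
This is deliberate: the self-training information values and the SCC
stopping statistic are defined on this squared-cost scale, and taking a
root (as several libraries do) would change them.  Argmin orderings are
unaffected, absolute values are not.

Series may have unequal lengths.  An optional Sakoe-Chiba-style band
width is accepted but defaults to unconstrained warping.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "local_cost",
    "accumulated_cost_matrix",
    "dtw_distance",
    "dtw_path",
    "pairwise_dtw",
]


def _as_series(x, name: str = "series") -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def local_cost(x: float, y: float) -> float:
    """Pointwise alignment cost d(x, y) = (x - y)^2."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("local_cost requires finite inputs")
    return float((x - y) ** 2)


@njit(cache=True)
def _acc_cost(a, b, window):  # pragma: no cover - exercised via wrappers
    m = a.shape[0]
    n = b.shape[0]
    D = np.empty((m + 1, n + 1), dtype=np.float64)
    D[0, 0] = 0.0
    for j in range(1, n + 1):
        D[0, j] = np.inf
    for i in range(1, m + 1):
        D[i, 0] = np.inf
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            if window >= 0 and abs(i - j) > window:
                D[i, j] = np.inf
                continue
            d = ai - b[j - 1]
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = d * d + best
    return D


@njit(cache=True)
def _backtrack(D):  # pragma: no cover - exercised via wrappers
    # Ties prefer the diagonal predecessor, then (i-1, j), then (i, j-1),
    # which makes the optimal path (and hence DBA) deterministic.
    m = D.shape[0] - 1
    n = D.shape[1] - 1
    maxlen = m + n - 1
    rev = np.empty((maxlen, 2), dtype=np.int64)
    i, j = m, n
    k = 0
    rev[k, 0] = i
    rev[k, 1] = j
    while i > 1 or j > 1:
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        k += 1
        rev[k, 0] = i
        rev[k, 1] = j
    path = np.empty((k + 1, 2), dtype=np.int64)
    for t in range(k + 1):
        path[t, 0] = rev[k - t, 0] - 1
        path[t, 1] = rev[k - t, 1] - 1
    return path


def accumulated_cost_matrix(a, b, window: int | None = None) -> np.ndarray:
    """Full (m+1) x (n+1) accumulated cost matrix with sentinel border.

    Entry ``D[i, j]`` (1-based interior) is the minimum summed squared
    cost of aligning the first ``i`` points of ``a`` with the first
    ``j`` points of ``b``; ``D[0, 0] = 0`` and the rest of row/column 0
    is infinite.
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    w = -1 if window is None else int(window)
    return _acc_cost(a, b, w)


def dtw_distance(a, b, window: int | None = None) -> float:
    """DTW distance: minimum summed squared cost over warping paths."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    w = -1 if window is None else int(window)
    return float(_acc_cost(a, b, w)[a.shape[0], b.shape[0]])


def dtw_path(a, b, window: int | None = None):
    """Optimal warping path and its cost.

    Returns ``(path, cost)`` where ``path`` is an (L, 2) integer array
    of 0-based index pairs starting at (0, 0) and ending at
    (len(a)-1, len(b)-1), each step moving by (1,1), (1,0) or (0,1).
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    w = -1 if window is None else int(window)
    D = _acc_cost(a, b, w)
    cost = float(D[a.shape[0], b.shape[0]])
    return _backtrack(D), cost


def pairwise_dtw(series_set, window: int | None = None) -> np.ndarray:
    """Symmetric look-up table of DTW distances for a set of series.

    Computed once and reused by the self-training loops, which turns the
    repeated nearest-labeled-neighbor queries into table reads.
    """
    series = [_as_series(s) for s in series_set]
    if len(series) == 0:
        raise ValueError("series_set must be non-empty")
    n = len(series)
    w = -1 if window is None else int(window)
    out = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(_acc_cost(series[i], series[j], w)[series[i].shape[0], series[j].shape[0]])
            out[i, j] = d
            out[j, i] = d
    return out
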
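"""Independent reference implementations used only to check the package.

These deliberately avoid the dynamic-programming recurrence of the
implementation under test: warping paths are enumerated explicitly, and
the memoized recursion computes the same minimum top-down from the
definition of the distance as a minimum over path costs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

STEPS = ((1, 1), (0, 1), (1, 0))


def enumerate_paths(m: int, n: int):
    """All monotone boundary-anchored warping paths of an m x n grid."""
    paths = []

    def walk(i, j, acc):
        if i == m - 1 and j == n - 1:
            paths.append(list(acc))
            return
        for di, dj in STEPS:
            ni, nj = i + di, j + dj
            if ni < m and nj < n:
                acc.append((ni, nj))
                walk(ni, nj, acc)
                acc.pop()

    walk(0, 0, [(0, 0)])
    return paths


def path_cost(a, b, path) -> float:
    return float(sum((a[i] - b[j]) ** 2 for i, j in path))


def brute_force_dtw(a, b) -> float:
    """Minimum summed squared cost over explicitly enumerated paths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return min(path_cost(a, b, p) for p in enumerate_paths(len(a), len(b)))


def brute_force_paths_argmin(a, b):
    """All optimal paths (for tie-break checks) and their shared cost."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    paths = enumerate_paths(len(a), len(b))
    costs = [path_cost(a, b, p) for p in paths]
    best = min(costs)
    return [p for p, c in zip(paths, costs) if c == best], best


def memoized_dtw(a, b) -> float:
    """Top-down memoized recursion on the distance definition."""
    a = tuple(float(x) for x in a)
    b = tuple(float(x) for x in b)

    @lru_cache(maxsize=None)
    def rec(i, j):
        d = (a[i] - b[j]) ** 2
        if i == 0 and j == 0:
            return d
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        return d + best

    return float(rec(len(a) - 1, len(b) - 1))


def all_int_series(max_len: int, alphabet=(0, 1, 2)):
    """Every integer-valued series of length 1..max_len over the alphabet."""
    out = []
    for length in range(1, max_len + 1):
        grids = np.meshgrid(*([list(alphabet)] * length), indexing="ij")
        stacked = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        out.extend(list(stacked))
    return out
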
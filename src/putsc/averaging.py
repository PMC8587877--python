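"""Time-series averaging: DBA barycenters and pointwise Euclidean means.

DBA (DTW barycenter averaging) refines an initial average sequence by
repeatedly (1) aligning every series of the set against the current
barycenter with DTW, (2) pooling, per barycenter position k, all series
elements whose optimal-path steps pair them with k, and (3) replacing
position k by the arithmetic mean of its pool.  The barycenter length is
fixed by the initializer — a uniformly random member of the set — and is
never resized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import _as_series, dtw_distance, dtw_path

__all__ = ["AverageSequence", "dba_iteration", "dba_average", "euclidean_average", "dba_objective"]


@dataclass
class AverageSequence:
    """A barycenter: its values, fixed length, and refinement count."""

    values: np.ndarray
    source_length: int
    iterations_run: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != self.source_length:
            raise ValueError("barycenter length must equal source_length")


def dba_iteration(current: AverageSequence | np.ndarray, series_set) -> AverageSequence:
    """One DBA refinement pass over the whole series set.

    The barycenter is always the *first* argument of the DTW alignment,
    and the diagonal-first backtracking tie-break fixes which elements
    populate each aligned set, so the result is deterministic.  The DTW
    boundary and continuity constraints guarantee every barycenter
    position receives at least one aligned element per series.
    """
    if isinstance(current, AverageSequence):
        center = current.values
        done = current.iterations_run
    else:
        center = _as_series(current, "current")
        done = 0
    series = [_as_series(s) for s in series_set]
    if len(series) == 0:
        raise ValueError("series_set must be non-empty")
    l = center.shape[0]
    sums = np.zeros(l, dtype=np.float64)
    counts = np.zeros(l, dtype=np.int64)
    for s in series:
        path, _ = dtw_path(center, s)
        np.add.at(sums, path[:, 0], s[path[:, 1]])
        np.add.at(counts, path[:, 0], 1)
    new = sums / counts
    return AverageSequence(new, l, done + 1)


def dba_average(
    series_set,
    iterations: int = 15,
    rng_seed: int | None = 0,
    *,
    init_index: int | None = None,
    early_stop: bool = False,
) -> AverageSequence:
    """DBA barycenter of a set of series.

    Parameters
    ----------
    series_set : sequence of 1-D arrays
        The set to average; lengths may differ.
    iterations : int
        Number of refinement passes (no convergence test by default).
    rng_seed : int or None
        Seed choosing the random initial barycenter among the members.
    init_index : int, optional
        Bypass the random draw and initialize from this member.
    early_stop : bool
        If True, stop early once an iteration leaves the barycenter
        bit-identical (off by default).
    """
    series = [_as_series(s) for s in series_set]
    if len(series) == 0:
        raise ValueError("series_set must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if init_index is None:
        rng = np.random.default_rng(rng_seed)
        init_index = int(rng.integers(len(series)))
    init = series[init_index]
    avg = AverageSequence(init.copy(), init.shape[0], 0)
    for _ in range(iterations):
        new = dba_iteration(avg, series)
        if early_stop and np.array_equal(new.values, avg.values):
            avg = new
            break
        avg = new
    return avg


def dba_objective(center, series_set) -> float:
    """Sum of DTW distances from the barycenter to every set member."""
    values = center.values if isinstance(center, AverageSequence) else center
    return float(sum(dtw_distance(values, s) for s in series_set))


def euclidean_average(series_set) -> np.ndarray:
    """Position-wise arithmetic mean; requires equal lengths.

    Pointwise averaging is undefined across unequal lengths, so those
    inputs raise instead of being silently truncated or padded.
    """
    series = [_as_series(s) for s in series_set]
    if len(series) == 0:
        raise ValueError("series_set must be non-empty")
    lengths = {s.shape[0] for s in series}
    if len(lengths) > 1:
        raise ValueError("euclidean_average requires equal-length series")
    return np.mean(np.vstack(series), axis=0)
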
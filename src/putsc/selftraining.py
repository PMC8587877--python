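"""Positive-unlabeled self-training loops and the SCC stopping rule.

Two label-propagation schedules are implemented:

* ``st_rank`` — classic self-training (the 1NN rule): at each iteration
  the unlabeled series closest to *any* currently labeled series joins
  the labeled set.  All distances come from a precomputed pairwise DTW
  look-up table, so the loop itself is O(|PL| * |U|) table reads.
* ``st_average_rank`` — self-training on the *average sequence*: each
  iteration recomputes the barycenter of the current labeled set (DBA
  under DTW, or a pointwise Euclidean mean) and selects the unlabeled
  series closest to that barycenter.  This is robust to labeled seeds
  sitting near the positive/negative boundary, where the 1NN rule can
  chain into the negative class.

Both record, per iteration, the info value: the minimum DTW distance
from the selected series to the labeled set at selection time.  The SCC
statistic turns that sequence into a stop index separating positives
from negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .averaging import dba_average, euclidean_average
from .dtw import _as_series, dtw_distance, pairwise_dtw

__all__ = [
    "PUDataset",
    "LabelingTrace",
    "SCCResult",
    "LabelingResult",
    "pu_pairwise_matrix",
    "st_rank",
    "st_average_rank",
    "scc",
    "finalize",
    "run_pipeline",
    "PipelineResult",
    "theoretical_speedup",
    "METHODS",
]

METHODS = ("st-scc", "scc-center-dtw", "scc-center-ed")


@dataclass
class PUDataset:
    """A seed positive-labeled set plus an unlabeled pool.

    ``truth`` optionally carries the hidden binary labels of the pool
    (1 = positive); it is only ever consulted by the evaluation layer.
    ``pl_indices`` / ``u_indices`` optionally record provenance into a
    parent labeled dataset.
    """

    pl: list
    u: list
    truth: np.ndarray | None = None
    pl_indices: np.ndarray | None = None
    u_indices: np.ndarray | None = None

    def __post_init__(self):
        self.pl = [_as_series(s, "PL series") for s in self.pl]
        self.u = [_as_series(s, "U series") for s in self.u]
        if not self.pl:
            raise ValueError("PL must be non-empty")
        if not self.u:
            raise ValueError("U must be non-empty")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=np.int64)
            if self.truth.shape[0] != len(self.u):
                raise ValueError("truth must have one label per unlabeled series")


@dataclass
class LabelingTrace:
    """Order in which the pool was labeled, with per-iteration info values.

    ``order`` holds 0-based indices into the original unlabeled pool; it
    is a permutation of ``range(|U|)``.  ``info[i]`` is the minimum DTW
    distance from the i-th selected series to the labeled set at the
    moment of its selection (squared-amplitude units).
    """

    order: np.ndarray
    info: np.ndarray

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=np.int64)
        self.info = np.asarray(self.info, dtype=np.float64)
        if self.order.shape != self.info.shape:
            raise ValueError("order and info must have equal length")


@dataclass
class SCCResult:
    """SCC statistic per iteration and the induced stop index.

    ``values[i-1]`` holds SCC(i) for iterations i = 2..|U| (1-based);
    position 0 is NaN because SCC needs a previous info value and a
    nonzero running standard deviation, neither of which exists at
    i = 1.  ``argmax_iteration`` is the winning 1-based iteration.
    """

    values: np.ndarray
    stop: int
    argmax_iteration: int


@dataclass
class LabelingResult:
    positive: list
    negative: list
    positive_u_indices: np.ndarray
    negative_u_indices: np.ndarray


def pu_pairwise_matrix(data: PUDataset, window: int | None = None) -> np.ndarray:
    """Pairwise DTW look-up table over the concatenation PL + U."""
    return pairwise_dtw(list(data.pl) + list(data.u), window=window)


def _check_matrix(data: PUDataset, distances: np.ndarray) -> np.ndarray:
    distances = np.asarray(distances, dtype=np.float64)
    n = len(data.pl) + len(data.u)
    if distances.shape != (n, n):
        raise ValueError(
            f"distance matrix must be {n}x{n} over PL+U, got {distances.shape}"
        )
    return distances


def st_rank(data: PUDataset, distances: np.ndarray | None = None) -> LabelingTrace:
    """Classic 1NN self-training ranking of the unlabeled pool.

    Iteratively moves the pool series with the smallest distance to its
    nearest labeled neighbor into the labeled set, until the pool is
    empty.  ``distances`` is a (|PL|+|U|) square matrix over the
    concatenation PL + U (computed on the fly when omitted).  Ties break
    toward the lowest original pool index.
    """
    if distances is None:
        distances = pu_pairwise_matrix(data)
    D = _check_matrix(data, distances)
    p, n = len(data.pl), len(data.u)
    # min distance from each pool member to the current labeled set
    mind = D[p:, :p].min(axis=1)
    remaining = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    info = np.empty(n, dtype=np.float64)
    for t in range(n):
        masked = np.where(remaining, mind, np.inf)
        x = int(np.argmin(masked))  # argmin returns the first = lowest index
        order[t] = x
        info[t] = mind[x]
        remaining[x] = False
        np.minimum(mind, D[p:, p + x], out=mind)
    return LabelingTrace(order, info)


def _subseed(master_seed: int, t: int) -> int:
    """Counter-based per-iteration sub-seed, kept below 2**31."""
    return int(np.random.SeedSequence([int(master_seed), int(t)]).generate_state(1)[0] % (2**31))


def st_average_rank(
    data: PUDataset,
    averager: str = "dba",
    dba_iterations: int = 15,
    master_seed: int = 0,
    distances: np.ndarray | None = None,
    *,
    center_distance_info: bool = False,
    window: int | None = None,
) -> LabelingTrace:
    """Average-sequence self-training ranking of the unlabeled pool.

    Each iteration recomputes the center of the current labeled set with
    the chosen averager ("dba" or "euclidean") and selects the pool
    series with the smallest DTW distance to the center.  The recorded
    info value is the minimum DTW distance from the selection to the
    current labeled set (pass ``center_distance_info=True`` to record
    the distance to the center instead, for sensitivity analysis).

    The DBA initializer is random; its seed for self-training iteration
    t is derived deterministically from ``master_seed`` and t, so a run
    is reproducible from the master seed alone.
    """
    if averager not in ("dba", "euclidean"):
        raise ValueError(f"unknown averager {averager!r}")
    if distances is None:
        distances = pu_pairwise_matrix(data, window=window)
    D = _check_matrix(data, distances)
    p, n = len(data.pl), len(data.u)
    labeled = list(data.pl)
    labeled_cols = list(range(p))
    remaining = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=np.int64)
    info = np.empty(n, dtype=np.float64)
    for t in range(n):
        if averager == "dba":
            center = dba_average(
                labeled, iterations=dba_iterations, rng_seed=_subseed(master_seed, t)
            ).values
        else:
            center = euclidean_average(labeled)
        cdist = np.full(n, np.inf)
        for x in range(n):
            if remaining[x]:
                cdist[x] = dtw_distance(data.u[x], center, window=window)
        x = int(np.argmin(cdist))
        order[t] = x
        pl_dist = D[p + x, labeled_cols].min()
        info[t] = cdist[x] if center_distance_info else pl_dist
        remaining[x] = False
        labeled.append(data.u[x])
        labeled_cols.append(p + x)
    return LabelingTrace(order, info)


def scc(
    info,
    u_size: int | None = None,
    *,
    std_flavor: str = "sample",
    stop_rule: str = "minus1",
) -> SCCResult:
    """Stopping-criterion confidence over an info sequence.

    SCC(i) = |info(i) - info(i-1)| / Std(info(1..i)) * (|U| - (i-1)) / |U|
    for iterations i = 2..|U|.  Degenerate ratios are defined as
    0/0 := 0 and positive/0 := +inf (such an iteration wins the argmax).
    ``stop`` is the argmax iteration minus 1 (``stop_rule="minus2"``
    selects the older argmax-minus-2 rule); argmax ties break toward
    the smallest iteration.
    """
    info = np.asarray(info, dtype=np.float64)
    if u_size is None:
        u_size = info.shape[0]
    if info.shape[0] != u_size:
        raise ValueError("info must have one value per unlabeled series")
    if u_size < 2:
        raise ValueError("SCC needs at least two labeling iterations")
    if std_flavor not in ("sample", "population"):
        raise ValueError(f"unknown std_flavor {std_flavor!r}")
    if stop_rule not in ("minus1", "minus2"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    ddof = 1 if std_flavor == "sample" else 0
    values = np.full(u_size, np.nan)
    for i in range(2, u_size + 1):
        jump = abs(info[i - 1] - info[i - 2])
        sd = float(np.std(info[:i], ddof=ddof))
        if sd == 0.0:
            ratio = 0.0 if jump == 0.0 else np.inf
        else:
            ratio = jump / sd
        values[i - 1] = ratio * (u_size - (i - 1)) / u_size
    argmax_iteration = 2 + int(np.argmax(values[1:]))  # first max = smallest i
    stop = argmax_iteration - (1 if stop_rule == "minus1" else 2)
    return SCCResult(values, stop, argmax_iteration)


def finalize(trace: LabelingTrace, stop: int, initial_pl, pool=None) -> LabelingResult:
    """Cut the labeling order at ``stop``: positives before, negatives after.

    The positive set is the initial labeled seeds plus the first
    ``stop`` selections; the negatives are every remaining selection.
    Together they partition the seeds plus the whole pool exactly.
    When ``pool`` (the original unlabeled series, in original order) is
    given, the result carries the series themselves as well as indices.
    """
    n = trace.order.shape[0]
    if not (0 <= stop <= n):
        raise ValueError(f"stop must lie in [0, {n}], got {stop}")
    pos_idx = trace.order[:stop].copy()
    neg_idx = trace.order[stop:].copy()
    positive = list(initial_pl)
    negative: list = []
    if pool is not None:
        positive += [pool[i] for i in pos_idx]
        negative = [pool[i] for i in neg_idx]
    return LabelingResult(
        positive=positive,
        negative=negative,
        positive_u_indices=pos_idx,
        negative_u_indices=neg_idx,
    )


@dataclass
class PipelineResult:
    trace: LabelingTrace
    scc_result: SCCResult
    labeling: LabelingResult
    predicted: np.ndarray  # 0/1 over the original pool order


def run_pipeline(
    data: PUDataset,
    method: str = "scc-center-dtw",
    *,
    dba_iterations: int = 15,
    master_seed: int = 0,
    stop_rule: str = "minus1",
    std_flavor: str = "sample",
    distances: np.ndarray | None = None,
    window: int | None = None,
) -> PipelineResult:
    """Label a PU dataset end to end: rank, SCC stop, final partition.

    Methods: ``st-scc`` (1NN self-training), ``scc-center-dtw``
    (DBA-barycenter self-training), ``scc-center-ed`` (Euclidean-mean
    self-training; equal lengths required).  All use DTW as the series
    distance and SCC as the stopping criterion.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if distances is None:
        distances = pu_pairwise_matrix(data, window=window)
    if method == "st-scc":
        trace = st_rank(data, distances)
    else:
        averager = "dba" if method == "scc-center-dtw" else "euclidean"
        trace = st_average_rank(
            data,
            averager=averager,
            dba_iterations=dba_iterations,
            master_seed=master_seed,
            distances=distances,
            window=window,
        )
    res = scc(trace.info, std_flavor=std_flavor, stop_rule=stop_rule)
    labeling = finalize(trace, res.stop, data.pl, pool=data.u)
    predicted = np.zeros(len(data.u), dtype=np.int64)
    predicted[trace.order[: res.stop]] = 1
    return PipelineResult(trace, res, labeling, predicted)


def theoretical_speedup(dba_iterations: int) -> int:
    """Asymptotic cost ratio of barycenter self-training over the 1NN loop.

    With a pairwise look-up table the 1NN loop costs O(N^2 L^2); adding
    the per-iteration DBA recomputation (I refinement passes each)
    raises this to O((I+1) N^2 L^2), so the 1NN variant is faster by a
    factor of I + 1.
    """
    if dba_iterations < 1:
        raise ValueError("dba_iterations must be >= 1")
    return int(dba_iterations) + 1
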
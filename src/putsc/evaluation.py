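"""Scoring and the repeated-random-initialization experiment harness.

Labeling quality is summarized by the F1 score of the predicted
positives over the *original unlabeled pool only* (the seeded positives
are known, so they are excluded from the confusion counts).  Methods
are compared across datasets by tie-averaged ranks of their mean F1.

The experiment protocol draws the positive seed set at random
``n_pl_draws`` times; methods whose barycenter initialization is itself
random (DBA) are additionally repeated ``n_dba_reps`` times per draw,
and the mean/std F1 is taken over all draw x repetition runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import LabeledDataset, make_pu_split
from .selftraining import METHODS, pu_pairwise_matrix, run_pipeline

__all__ = [
    "ConfusionSummary",
    "precision_recall",
    "f1_score",
    "confusion_from_labels",
    "tie_average_ranks",
    "ExperimentConfig",
    "MethodSummary",
    "ExperimentSummary",
    "run_experiment",
    "aggregate_rank_table",
]


@dataclass
class ConfusionSummary:
    """Counts needed for precision/recall on the positive class."""

    correct_positive_predictions: int
    positive_predictions: int
    positive_instances: int

    def __post_init__(self):
        c, p, a = (
            self.correct_positive_predictions,
            self.positive_predictions,
            self.positive_instances,
        )
        if min(c, p, a) < 0:
            raise ValueError("counts must be nonnegative")
        if c > min(p, a):
            raise ValueError(
                "correct positive predictions cannot exceed predictions or instances"
            )


def precision_recall(cs: ConfusionSummary) -> tuple[float, float]:
    p = cs.correct_positive_predictions / cs.positive_predictions if cs.positive_predictions else 0.0
    r = cs.correct_positive_predictions / cs.positive_instances if cs.positive_instances else 0.0
    return p, r


def f1_score(cs: ConfusionSummary) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    p, r = precision_recall(cs)
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def confusion_from_labels(predicted, truth) -> ConfusionSummary:
    """Confusion counts from 0/1 predicted and true pool labels."""
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    return ConfusionSummary(
        correct_positive_predictions=int(np.sum((predicted == 1) & (truth == 1))),
        positive_predictions=int(np.sum(predicted == 1)),
        positive_instances=int(np.sum(truth == 1)),
    )


def tie_average_ranks(scores, higher_is_better: bool = True) -> np.ndarray:
    """Competition ranks (best = 1) with ties sharing the mean position."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    return rankdata(-scores if higher_is_better else scores, method="average")


@dataclass
class ExperimentConfig:
    """Knobs of the labeling experiment; defaults follow the study protocol
    of 3 seed positives, 15 DBA refinement passes, 20 random seed-set
    draws and 20 DBA repetitions per draw."""

    methods: tuple = METHODS
    positive_label: int = 1
    pl_size: int = 3
    dba_iterations: int = 15
    n_pl_draws: int = 20
    n_dba_reps: int = 20
    seed: int = 0
    stop_rule: str = "minus1"
    std_flavor: str = "sample"
    boundary_seed: bool = False
    window: int | None = None


@dataclass
class MethodSummary:
    method: str
    mean_f1: float
    std_f1: float
    runs: int
    rank: float = float("nan")
    f1_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass
class ExperimentSummary:
    dataset: str
    methods: list  # of MethodSummary, in config order

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset": self.dataset,
                "method": m.method,
                "mean_f1": m.mean_f1,
                "std_f1": m.std_f1,
                "runs": m.runs,
                "rank": m.rank,
            }
            for m in self.methods
        ]
        return pd.DataFrame(rows)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_experiment(dataset: LabeledDataset, config: ExperimentConfig) -> ExperimentSummary:
    """Run every configured method over repeated random seed-set draws.

    The pairwise DTW look-up table over the whole dataset is computed
    once and sliced per split, so only the per-iteration barycenters
    require fresh DTW work.  F1 dispersion is the sample (ddof = 1)
    standard deviation over runs; a single run reports std 0.
    Deterministic given ``config.seed``.
    """
    n_pos = int(np.sum(dataset.labels == config.positive_label))
    if n_pos < config.pl_size:
        raise ValueError(
            f"dataset has {n_pos} positives, fewer than pl_size={config.pl_size}"
        )
    for m in config.methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")

    from .dtw import pairwise_dtw

    full = pairwise_dtw(dataset.series, window=config.window)
    summaries = []
    for m_i, method in enumerate(config.methods):
        reps = config.n_dba_reps if method == "scc-center-dtw" else 1
        f1s = []
        for draw in range(config.n_pl_draws):
            split_seed = _derived_seed(config.seed, draw)
            data = make_pu_split(
                dataset,
                positive_label=config.positive_label,
                pl_size=config.pl_size,
                seed=split_seed,
                boundary_seed=config.boundary_seed,
            )
            order = np.concatenate([data.pl_indices, data.u_indices])
            distances = full[np.ix_(order, order)]
            for rep in range(reps):
                result = run_pipeline(
                    data,
                    method,
                    dba_iterations=config.dba_iterations,
                    master_seed=_derived_seed(config.seed, draw, rep, m_i),
                    stop_rule=config.stop_rule,
                    std_flavor=config.std_flavor,
                    distances=distances,
                    window=config.window,
                )
                f1s.append(f1_score(confusion_from_labels(result.predicted, data.truth)))
        f1s = np.asarray(f1s)
        std = float(np.std(f1s, ddof=1)) if f1s.size > 1 else 0.0
        summaries.append(
            MethodSummary(method, float(np.mean(f1s)), std, int(f1s.size), f1_values=f1s)
        )
    if len(summaries) > 1:
        ranks = tie_average_ranks([m.mean_f1 for m in summaries])
        for m, r in zip(summaries, ranks):
            m.rank = float(r)
    return ExperimentSummary(dataset.name, summaries)


def aggregate_rank_table(rank_frame: pd.DataFrame) -> pd.DataFrame:
    """Average ranking row over datasets: mean and population std per method.

    ``rank_frame`` is indexed by dataset with one column per method.
    The dispersion uses the population (ddof = 0) standard deviation —
    the convention for summarizing a fixed grid of per-dataset ranks.
    """
    return pd.DataFrame(
        {
            "mean_rank": rank_frame.mean(axis=0),
            "std_rank": rank_frame.std(axis=0, ddof=0),
        }
    )
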
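"""UCR-style dataset I/O, PU-split construction, and synthetic generators.

The UCR archive convention is one series per line of a delimited text
file: an integer class label first, then the real-valued observations,
tab- or comma-separated.  Variable-length series are supported by
dropping empty trailing fields.

Two generators keep every stage testable without downloads:

* ``generate_cbf`` — the classic cylinder/bell/funnel three-class
  simulated benchmark.
* ``generate_boundary_scenario`` — a two-class fixture that reproduces
  the failure mode motivating barycenter-based self-training: some
  positive seeds sit right at the class boundary, adjacent to a
  "decoy" negative that bridges into a dense negative band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import _as_series
from .selftraining import PUDataset

__all__ = [
    "LabeledDataset",
    "read_ucr",
    "write_ucr",
    "znormalize",
    "make_pu_split",
    "generate_cbf",
    "generate_boundary_scenario",
]


@dataclass
class LabeledDataset:
    """Series with integer class labels; ``meta`` carries generator facts."""

    series: list
    labels: np.ndarray
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.series = [_as_series(s) for s in self.series]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.series) != self.labels.shape[0]:
            raise ValueError("series and labels must have equal length")

    def __len__(self) -> int:
        return len(self.series)


def znormalize(values: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance scaling of one series (constant -> zeros)."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()
    if sd == 0.0:
        return values - values.mean()
    return (values - values.mean()) / sd


def read_ucr(path, name: str | None = None, normalize: bool = False) -> LabeledDataset:
    """Read a UCR-style delimited text file.

    The delimiter (tab or comma) is sniffed from the first data line.
    Labels are parsed as integers (tolerating float spellings like
    ``1.0``), values as reals; empty trailing fields — the common
    encoding of variable-length series — are dropped.  Per-series
    z-normalization is applied when ``normalize`` is True (UCR data are
    commonly pre-normalized, so the default is off).
    """
    series: list = []
    labels: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            delim = "\t" if "\t" in line else ","
            fields = line.split(delim)
            while fields and fields[-1].strip() == "":
                fields.pop()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need a label and at least one value")
            try:
                labels.append(int(float(fields[0])))
                values = np.array([float(v) for v in fields[1:]], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            series.append(znormalize(values) if normalize else values)
    if not series:
        raise ValueError(f"{path}: empty dataset")
    import os

    return LabeledDataset(series, np.array(labels), name or os.path.basename(str(path)))


def write_ucr(ds: LabeledDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset in UCR delimited-text form (label first)."""
    if delimiter not in ("\t", ","):
        raise ValueError("delimiter must be tab or comma")
    with open(path, "w") as fh:
        for label, s in zip(ds.labels, ds.series):
            fields = [str(int(label))] + [repr(float(v)) for v in s]
            fh.write(delimiter.join(fields) + "\n")


def make_pu_split(
    ds: LabeledDataset,
    positive_label: int = 1,
    pl_size: int = 3,
    seed: int | None = 0,
    *,
    boundary_seed: bool = False,
) -> PUDataset:
    """Split a labeled dataset into positive seeds and an unlabeled pool.

    ``pl_size`` positives are drawn uniformly without replacement; the
    pool is *every* remaining instance (positive and negative) in the
    original dataset order, with its hidden binary ground truth kept
    for evaluation only.

    ``boundary_seed=True`` forces one seed to come from the generator's
    designated boundary-adjacent positives (``meta["boundary_indices"]``)
    and draws the rest from the interior positives — the adverse
    initialization that 1NN self-training is sensitive to.
    """
    pos_idx = np.flatnonzero(ds.labels == positive_label)
    if pos_idx.shape[0] < pl_size:
        raise ValueError(
            f"dataset has {pos_idx.shape[0]} instances of label {positive_label}, "
            f"need at least pl_size={pl_size}"
        )
    rng = np.random.default_rng(seed)
    if boundary_seed:
        boundary = np.asarray(ds.meta.get("boundary_indices", []), dtype=np.int64)
        boundary = boundary[np.isin(boundary, pos_idx)]
        if boundary.size == 0:
            raise ValueError("dataset declares no boundary positives to seed from")
        interior = pos_idx[~np.isin(pos_idx, boundary)]
        if interior.shape[0] < pl_size - 1:
            raise ValueError("not enough interior positives for boundary seeding")
        chosen = np.concatenate(
            [
                rng.choice(boundary, size=1, replace=False),
                rng.choice(interior, size=pl_size - 1, replace=False),
            ]
        )
    else:
        chosen = rng.choice(pos_idx, size=pl_size, replace=False)
    chosen = np.sort(chosen)
    mask = np.ones(len(ds), dtype=bool)
    mask[chosen] = False
    u_idx = np.flatnonzero(mask)
    return PUDataset(
        pl=[ds.series[i] for i in chosen],
        u=[ds.series[i] for i in u_idx],
        truth=(ds.labels[u_idx] == positive_label).astype(np.int64),
        pl_indices=chosen,
        u_indices=u_idx,
    )


def generate_cbf(
    n_per_class: int,
    length: int = 128,
    seed: int | None = 0,
    *,
    noise_std: float = 1.0,
    amplitude_std: float = 1.0,
) -> LabeledDataset:
    """Cylinder-bell-funnel simulated dataset (labels 1, 2, 3).

    Each series places a pattern of amplitude 6 + eta (eta ~ N(0,
    ``amplitude_std``)) on a plateau [a, b] with onset a ~ U{16..32}
    and duration b - a ~ U{32..96}, plus N(0, ``noise_std``) noise:
    cylinder (label 1) is flat, bell (label 2) ramps linearly up across
    [a, b], funnel (label 3) ramps linearly down.  Setting both spread
    parameters to 0 gives the noiseless patterns (test hook).
    """
    if length < 32:
        raise ValueError("length must be >= 32 for the onset/duration ranges")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(1, length + 1, dtype=np.float64)
    series, labels = [], []
    for label, shape in ((1, "cylinder"), (2, "bell"), (3, "funnel")):
        for _ in range(n_per_class):
            a = int(rng.integers(16, 33))
            b = a + int(rng.integers(32, 97))
            b = min(b, length)
            amp = 6.0 + amplitude_std * rng.standard_normal()
            on = ((t >= a) & (t <= b)).astype(np.float64)
            if shape == "cylinder":
                profile = on
            elif shape == "bell":
                profile = on * (t - a) / (b - a)
            else:
                profile = on * (b - t) / (b - a)
            x = amp * profile + noise_std * rng.standard_normal(length)
            series.append(x)
            labels.append(label)
    return LabeledDataset(series, np.array(labels), name="cbf")


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def generate_boundary_scenario(
    n_pos: int = 17,
    n_neg: int = 24,
    overlap: float = 1.0,
    seed: int | None = 0,
    *,
    length: int = 64,
    noise_std: float = 0.005,
) -> LabeledDataset:
    """Two-class fixture with a boundary-adjacent positive seed (label 1 = positive).

    Every series carries two rectangular pulses whose *heights*
    (h1, h2) encode the class; pulse positions jitter by whole samples —
    a time shift DTW absorbs but pointwise comparison does not.
    Rectangular (rather than smooth) pulses keep the DTW geometry
    linear in height space: warping cannot trade a height difference
    for an alignment onto a pulse flank, so the distance between two
    series is essentially pulse-width x the squared height gap.  Interior
    positives sit on a spaced grid in height space (spacing 0.12 per
    axis from (0.2, 0.2)); one *boundary* positive sits 0.15 beyond
    the grid's top corner along the diagonal.  Negatives are a "decoy"
    a further 0.05 + 1.5(1 - overlap) along the diagonal, then a graded
    band walking outward from the decoy.

    The margins are sized so that at ``overlap = 1`` the decoy is
    closer (in squared-cost DTW) to the boundary positive than any two
    positives are to each other, and the dense band continues from the
    decoy in still smaller steps: a 1NN self-training seeded at the
    boundary labels the decoy first and chains deep into the negative
    band, while the barycenter of the labeled set stays near the
    positive-class mean — which the grid keeps compact, so every hidden
    positive is nearer the barycenter than the decoy is.  At
    ``overlap = 0`` the classes are far apart and every method labels
    the pool perfectly.  The boundary positive occupies index 0 and is
    declared in ``meta["boundary_indices"]`` (in-memory only; the UCR
    text format does not carry it).
    """
    if n_pos < 3 or n_neg < 3:
        raise ValueError("need at least 3 instances per class")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    if length < 48:
        raise ValueError("length must be >= 48 to hold both bumps and their jitter")
    rng = np.random.default_rng(seed)
    t = np.arange(length, dtype=np.float64)
    width = 12  # pulse width in samples
    spacing = 0.12
    diag = 1.0 / np.sqrt(2.0)

    n_interior = n_pos - 1
    side = int(np.ceil(np.sqrt(n_interior)))
    grid = [
        (0.2 + spacing * (k % side), 0.2 + spacing * (k // side))
        for k in range(n_interior)
    ]
    corner = 0.2 + spacing * (side - 1)
    boundary = corner + 0.15 * diag
    decoy = boundary + (0.05 + 1.5 * (1.0 - overlap)) * diag
    jit = lambda: rng.uniform(-0.002, 0.002)

    pos_heights = [(boundary + jit(), boundary + jit())] + [
        (a + jit(), b + jit()) for a, b in grid
    ]
    # band: a graded outward walk from the decoy, steps comparable to the
    # decoy gap, so the 1NN chain keeps walking and the info sequence has
    # no second cliff after the decoy
    steps = rng.uniform(0.06, 0.10, n_neg - 1)
    steps[0] = 0.1
    neg_heights = [(decoy + jit(), decoy + jit())]
    for q in decoy + np.cumsum(steps) * diag:
        neg_heights.append((q + rng.uniform(-0.01, 0.01), q + rng.uniform(-0.01, 0.01)))

    series, labels = [], []
    for (h1, h2), label in [(h, 1) for h in pos_heights] + [(h, 2) for h in neg_heights]:
        s1 = int(length * 0.16) + int(rng.integers(-2, 3))  # integer shifts: free under DTW
        s2 = int(length * 0.60) + int(rng.integers(-2, 3))
        x = noise_std * rng.standard_normal(length)
        x[s1 : s1 + width] += h1
        x[s2 : s2 + width] += h2
        series.append(x)
        labels.append(label)
    return LabeledDataset(
        series,
        np.array(labels),
        name="boundary-scenario",
        meta={"boundary_indices": [0]},
    )
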
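# Methods

## Distance

All similarity in the package is dynamic time warping over the squared
local cost d(x, y) = (x − y)².  A warping path W = (w₁, …, w_L) pairs
indices of two series A (length m) and B (length n) subject to the
boundary constraint (w₁ = (1,1), w_L = (m,n)) and the
continuity/monotonicity constraint (steps of (1,1), (0,1) or (1,0));
DTW(A, B) is the minimum over paths of the summed local costs, computed
by the standard accumulated-cost recurrence in O(mn).  **No square root
is taken**: the info values and the SCC statistic live on this squared
scale, so replacing the distance with its root (as many libraries do)
would change their values even though argmin orderings are unaffected.
Unequal lengths are fully supported.  An optional warping-band width
exists for experimentation but defaults to unconstrained, which is what
every method here uses.

Backtracking ties are broken deterministically: diagonal first, then
(i−1, j), then (i, j−1).  This makes optimal paths — and everything
downstream of them, in particular DBA — reproducible bit-for-bit.

The self-training loops consult a precomputed symmetric pairwise DTW
table over PL ∪ U (`pairwise_dtw`); only distances to freshly computed
barycenters are evaluated on demand.

## Averaging

`dba_average` implements DTW barycenter averaging: the initial
barycenter is a uniformly random member of the set (seeded); each
refinement pass aligns every series against the current barycenter
(barycenter as the first DTW argument), pools per barycenter position
the series elements its optimal-path steps touch, and replaces the
position by the pool mean.  The barycenter length is fixed by the
initializer and never resized; the wider search over all candidate
lengths is deliberately not performed.  Exactly `iterations` passes are
run (default 15); an opt-in early exit triggers only when a pass leaves
the barycenter bit-identical.  The DBA objective — the sum of DTW
distances from the barycenter to the set — is non-increasing across
passes, which the tests assert on 50 seeded random sets.

`euclidean_average` is the position-wise mean and requires equal
lengths; unequal-length input is an error rather than a silently padded
guess.

## Labeling loops

`st_rank` (1NN self-training) repeatedly moves the pool series with the
smallest distance to its nearest labeled neighbor into the labeled set.
`st_average_rank` recomputes the labeled set's center each iteration —
DBA barycenter or pointwise mean — and selects the pool series nearest
the center.  In both loops info(i) is the minimum DTW distance from the
selected series to the labeled set at selection time; a center-distance
variant of info is available behind a flag for sensitivity analysis but
is not the default, since the labeled-set distance is what the stopping
statistic is defined on.  Selection ties break toward the lowest
original pool index, making reruns deterministic.

Seeds: a run takes one master seed; the DBA initializer seed for
self-training iteration t is derived as SeedSequence([master_seed, t])
(counter-based, below 2³¹), so a trace is reproducible from the master
seed alone and consecutive iterations get independent initializers.
Whether the original experiments re-drew the DBA initializer every
self-training iteration or reused one is not specified anywhere we know
of; re-drawing per iteration is this package's choice.

## Stopping

SCC(i) is defined for iterations i ∈ [2, |U|]: it needs info(i−1) and a
running standard deviation, neither of which exists at i = 1, so the
first iteration is excluded from the argmax.  The standard deviation is
the sample flavor (ddof = 1) by default with a population flag.
Degenerate ratios are defined as 0/0 := 0 and positive/0 := +∞; note
the +∞ branch is actually unreachable through the formula as written —
Std(info(1..i)) includes info(i), so a nonzero jump forces a nonzero
denominator — and is kept purely as defensive code.  The default stop
is argmax − 1; the older argmax − 2 convention is selectable.  Argmax
ties break toward the smallest iteration.

A structural property of SCC worth knowing (it shaped the synthetic
scenario below): because the deviation is taken over the prefix
*including* the jump, a spike after a flat prefix scores at most
√i · (|U| − i + 1)/|U| regardless of the spike's size, while
noise-driven ratios on near-constant prefixes reach ≈ 2.  Clean cuts
therefore need the class transition to occur at a late-enough iteration
and the within-class info sequence to be uniform.

## Evaluation protocol

Labeling quality is the F1 of the predicted positives over the original
pool only (the given seeds are excluded from the confusion counts),
with p := 0 when nothing is predicted positive and F1 := 0 when
p + r = 0.  The experiment harness draws the seed set at random
`n_pl_draws` times (default 20) with `pl_size` = 3 seeds and, for the
DBA-based method, repeats each draw `n_dba_reps` times (default 20)
with fresh barycenter initializers, reporting mean and sample-std F1
over all runs.  Methods are compared by tie-averaged ranks of mean F1
(best = 1; ties share the mean of their positions); the average-ranking
summary across datasets uses the population (ddof = 0) standard
deviation, the convention consistent with summarizing a fixed grid of
per-dataset ranks, while F1 dispersion is a run-level sample statistic.

## Synthetic data

`generate_cbf` is the classic cylinder/bell/funnel simulator: an
amplitude-(6 + η) pattern on a random plateau [a, b] (a ~ U{16..32},
b − a ~ U{32..96}) plus unit Gaussian noise; flat, ramp-up and
ramp-down profiles give the three classes.  Setting the two spread
parameters to zero exposes the noiseless patterns for shape tests.

`generate_boundary_scenario` reproduces, as a measurable fixture, the
failure mode that motivates barycenter-driven self-training: labeled
seeds adjacent to the class boundary.  Each series carries two
rectangular pulses whose heights (h₁, h₂) encode the class and whose
positions jitter by whole samples — a time shift DTW absorbs but
pointwise comparison does not.  Rectangular rather than smooth pulses
keep the DTW geometry linear in height space: a smooth bump lets
warping align a lower peak onto a taller bump's flank, compressing
large height differences and eroding the designed margins, whereas for
rectangular pulses the distance is exactly pulse-width × squared height
gap.  Interior positives sit on a 4 × 4 height grid (spacing 0.12 from
(0.2, 0.2)) — compact, so the barycenter stays central and every hidden
positive is nearer to it than any negative; one boundary positive sits
0.15 beyond the grid's corner; the decoy negative is 0.05 + 1.5(1 −
overlap) further, and the remaining negatives walk outward in graded
steps of 0.06–0.10 so the 1NN chain, once it has absorbed the decoy,
keeps walking and the info sequence has no second cliff.  Noise is
N(0, 0.005) per sample.  At overlap = 1 (the default, fully adjacent
boundary) a boundary-seeded 1NN run labels the decoy first and chains
through the negative band — F1 collapses — while the barycenter run
orders positives first and usually cuts exactly at the transition; at
overlap = 0 the classes are far apart and all methods rank the pool
perfectly.  The residual imperfection is informative: the very first
selection's info can be an outlier (its distance to sparse seeds, on
the squared scale, may span several grid steps), which inflates the
running deviation and occasionally pulls the SCC argmax early.  That is
an inherent sensitivity of the statistic, not of the selection rule.

What the fixture does not emulate: real series have correlated noise,
within-class shape variation beyond amplitude, and class structure not
reducible to a low-dimensional height space; passing these tests shows
the algorithms implement the intended geometry-dependent behaviors, not
that they reach any particular F1 on real recordings.  UCR-style files
are read directly for real-data use; per-series z-normalization is an
opt-in flag at the I/O layer (off by default, since archived data are
commonly pre-normalized and nothing in the method requires it).

## Numerical and interface choices

Problem sizes in tests and the acceptance script are chosen for tight
feedback: exhaustive oracle grids up to length 5, pools of ~40 series
of length 64, 20 initializations per comparison.  DBA's objective
descent is asserted to 1e−9; path and distance agreement is exact.
Errors are typed: invalid series (empty, non-finite) and violated
preconditions raise ValueError; the CLI maps usage errors to exit code
2 and data errors to exit code 3, always writes the trace (it is the
primary debugging artifact, even when the stop degenerates to a range
edge), and logs seed, config digest, stop index and counts to stderr so
a run can be reproduced from its log alone.
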
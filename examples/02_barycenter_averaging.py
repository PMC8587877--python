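"""Averaging time-shifted bumps: DBA barycenter vs pointwise mean.

Six copies of one bump, each shifted in time.  The pointwise mean
smears the bump into a low, wide mound; the DBA barycenter re-aligns
the copies before averaging and stays bump-shaped, which shows up as a
much smaller mean DTW distance to the set.
"""

import numpy as np

from putsc import dtw_distance, euclidean_average
from putsc.averaging import dba_average

rng = np.random.default_rng(0)
length, width = 40, 3.0
t = np.arange(length)
series = [
    np.exp(-0.5 * ((t - c) / width) ** 2)
    for c in rng.uniform(length * 0.25, length * 0.75, 6)
]

bary = dba_average(series, iterations=15, rng_seed=0).values
mean = euclidean_average(series)

fit = lambda center: float(np.mean([dtw_distance(center, s) for s in series]))
print(f"mean DTW to the set, DBA barycenter: {fit(bary):.4f}")
print(f"mean DTW to the set, pointwise mean: {fit(mean):.4f}")
print(f"peak height, DBA barycenter:         {bary.max():.3f}")
print(f"peak height, pointwise mean:         {mean.max():.3f}")
print()
print("The barycenter preserves the bump's amplitude (close to the true 1.0)")
print("while the pointwise mean flattens it — the reason the barycenter is")
print("the representative sequence used by average-based self-training.")
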
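import numpy as np
import pytest

# Two heartbeat-style sequences that are exact time-warped duplicates of
# each other: under squared-cost DTW their distance is zero although they
# are pointwise different.
WARPED_TWIN_A = (1, 1, 2, 2.5, 3, 3, 3, 3, 2.5, 2.5, 2, 2, 1, 1)
WARPED_TWIN_B = (1, 1, 1, 2, 2.5, 3, 3, 3, 2.5, 2, 2, 2, 1, 1)


@pytest.fixture
def warped_twins():
    return np.array(WARPED_TWIN_A, float), np.array(WARPED_TWIN_B, float)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_series_pairs(n_pairs, max_len=5, alphabet=(0, 1, 2), seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        la, lb = rng.integers(1, max_len + 1, size=2)
        pairs.append(
            (
                rng.choice(alphabet, size=la).astype(float),
                rng.choice(alphabet, size=lb).astype(float),
            )
        )
    return pairs
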
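import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fmridyn as fd

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_series():
    """A 10x10x8x60 random BOLD series with an interior box mask."""
    r = np.random.default_rng(7)
    data = r.standard_normal((10, 10, 8, 60))
    mask = np.zeros((10, 10, 8), dtype=bool)
    mask[1:9, 1:9, 1:7] = True
    return fd.BoldSeries(data, voxel_size=[3.0, 3.0, 3.0], tr=2.0, mask=mask)


def brute_force_w(ratings):
    """Loop-based Kendall's W from first principles (independent oracle).

    Ranks each judge by explicit counting (average ranks for ties), then
    accumulates the rank-sum deviations and tie corrections with plain
    Python loops.
    """
    ratings = np.asarray(ratings, dtype=float)
    m, n = ratings.shape
    ranks = np.empty_like(ratings)
    tie_sum = 0.0
    for j in range(m):
        row = ratings[j]
        for i in range(n):
            less = sum(1 for v in row if v < row[i])
            equal = sum(1 for v in row if v == row[i])
            ranks[j, i] = less + (equal + 1) / 2.0
        for v in set(row):
            t = int(sum(1 for x in row if x == v))
            if t > 1:
                tie_sum += t**3 - t
    S = 0.0
    for i in range(n):
        R_i = sum(ranks[j, i] for j in range(m))
        S += (R_i - m * (n + 1) / 2.0) ** 2
    denom = m**2 * (n**3 - n) - m * tie_sum
    if denom <= 0:
        return float("nan")
    return 12.0 * S / denom


@pytest.fixture(scope="session")
def w_oracle():
    return brute_force_w
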
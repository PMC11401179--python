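import numpy as np
import pytest


@pytest.fixture(scope="session")
def structured_R():
    """Correlation kernel with low-rank structure (well-identified model)."""
    rng = np.random.default_rng(7)
    F = rng.standard_normal((100, 8))
    return np.corrcoef(F)


@pytest.fixture(scope="session")
def covariates_100():
    rng = np.random.default_rng(11)
    return rng.standard_normal((100, 5))


def brute_force_sampen(x, m=2, eps=0.2):
    """Independent O(N^2) double-loop oracle for sample entropy, following
    the textbook definition term by term."""
    x = np.asarray(x, float)
    N = len(x)
    sigma = np.sqrt(np.mean((x - x.mean()) ** 2))
    r = eps * sigma
    nv = N - m
    count_m = 0
    count_m1 = 0
    for i in range(nv):
        for j in range(nv):
            if i == j:
                continue
            d_m = 0.0
            for k in range(m):
                d_m = max(d_m, abs(x[i + k] - x[j + k]))
            if d_m <= r:
                count_m += 1
            d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
            if d_m1 <= r:
                count_m1 += 1
    if count_m == 0 or count_m1 == 0:
        return float("nan")
    return -np.log(count_m1 / count_m)
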
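import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230719)


def random_design(rng, n_max: int = 200):
    """Random valid (n, N0, r) with 0 < n < N0 and r > 0."""
    n = int(rng.integers(2, n_max))
    N0 = int(rng.integers(n + 1, 2 * n_max))
    r = float(rng.uniform(0.5, 3.0 * N0))
    return n, N0, r
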
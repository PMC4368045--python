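import numpy as np
import pytest


def random_psd(rng, k, scale=1.0):
    """Random positive semi-definite k x k matrix."""
    A = rng.normal(scale=scale, size=(k, k))
    return A @ A.T


def random_instance(rng, max_n=200, max_k=3):
    """Random (Z, Sigma) pair for trace-identity style checks."""
    n = int(rng.integers(2, max_n + 1))
    k = int(rng.integers(1, max_k + 1))
    Z = rng.normal(size=(n, k))
    if k > 1 and rng.random() < 0.5:
        Z[:, 0] = 1.0  # include a random intercept half the time
    return Z, random_psd(rng, k)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
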
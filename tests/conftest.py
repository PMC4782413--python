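import numpy as np
import pytest


def random_instance(seed, n=6, p=4, phi=0.7):
    """Small random (y, mu, phi, X) instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.poisson(5.0, n)
    mu = rng.uniform(1.0, 5.0, n)
    return y, mu, phi, X


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
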
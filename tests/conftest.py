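import numpy as np
import pytest

from hopflow.network import HopfieldNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def random_network(rng, n, scale=1.0):
    """Gaussian symmetric zero-diagonal weights and Gaussian thresholds."""
    A = rng.normal(size=(n, n), scale=scale)
    W = (A + A.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return HopfieldNetwork(W, rng.normal(size=n, scale=scale))


def random_distribution(rng, size):
    q = rng.random(size)
    return q / q.sum()
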
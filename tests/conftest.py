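import numpy as np
import pytest

from cliquehop.core import HopfieldNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(n: int, rng: np.random.Generator, scale: float = 1.0) -> HopfieldNetwork:
    A = rng.normal(scale=scale, size=(n, n))
    W = 0.5 * (A + A.T)
    np.fill_diagonal(W, 0.0)
    theta = rng.normal(scale=scale, size=n)
    return HopfieldNetwork(W, theta)


@pytest.fixture
def random_net_factory(rng):
    def make(n: int, scale: float = 1.0) -> HopfieldNetwork:
        return random_network(n, rng, scale)

    return make
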
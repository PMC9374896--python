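import numpy as np
import pytest

from spdstates.riemann import _symmetrize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, n, cond_scale=1.0):
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((n, n))
    return _symmetrize(A @ A.T + cond_scale * n * np.eye(n))


@pytest.fixture
def spd_factory(rng):
    def make(n, cond_scale=1.0):
        return random_spd(rng, n, cond_scale)
    return make
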
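import numpy as np
import pytest

from floodrisk import coda


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_compositions(rng, n, d, scale=1.0):
    """Logistic-normal draws: well-spread strictly positive compositions."""
    return coda.clr_inv(
        scale * rng.standard_normal((n, d))
        - scale * rng.standard_normal((n, 1))
    )


@pytest.fixture
def comp_pair(rng):
    x, y = random_compositions(rng, 2, 6)
    return x, y
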
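import numpy as np
import pytest

from medfuse.phantoms import PhantomSpec, make_pair


@pytest.fixture(scope="session")
def default_pair():
    """Default 128x128 phantom pair with ground truth."""
    return make_pair(PhantomSpec())


@pytest.fixture(scope="session")
def small_pair():
    """64x64 phantom pair for fast full-pipeline tests."""
    return make_pair(PhantomSpec(size=64))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_image(rng, shape=(16, 16), eight_bit=False):
    if eight_bit:
        return rng.integers(0, 256, size=shape).astype(np.float64) / 255.0
    return rng.random(shape)
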
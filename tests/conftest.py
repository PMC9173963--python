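import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """16×16 grayscale image with intensities bounded away from zero."""
    return rng.uniform(20.0, 255.0, (16, 16))


def make_images(rng, n, shape=(16, 16), lo=20.0, hi=255.0):
    return [rng.uniform(lo, hi, shape) for _ in range(n)]
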
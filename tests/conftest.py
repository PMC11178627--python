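import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 16x16 image with full dynamic range."""
    img = rng.uniform(size=(16, 16))
    img[0, 0], img[-1, -1] = 0.0, 1.0
    return img


def random_images(n, shape=(16, 16), seed=0):
    """n independent uniform images at the given shape."""
    rng = np.random.default_rng(seed)
    return [rng.uniform(size=shape) for _ in range(n)]
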
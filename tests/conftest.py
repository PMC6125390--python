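import numpy as np
import pytest

from histofract.image_prep import BinImage, GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mask(rng):
    """Seeded 32x32 mask with ~40% foreground."""
    return BinImage(rng.random((32, 32)) < 0.4)


@pytest.fixture
def random_gray(rng):
    return GrayImage(rng.integers(0, 256, (64, 64), dtype=np.int64))
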
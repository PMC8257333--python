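import numpy as np
import pytest

from angioseg.image_io import BinaryMask, GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_plateau():
    """60x60 image: left half 0, right half 255."""
    img = np.zeros((60, 60))
    img[:, 30:] = 255.0
    return GrayImage(img)


@pytest.fixture
def disc_phantom():
    """50x50 disc of intensity 40 on background 200, Gaussian noise sd 2.

    Built directly with numpy (independent of the phantom module) so it
    can serve as ground truth for region-growing tests.
    """
    gen = np.random.default_rng(77)
    rr, cc = np.mgrid[0:50, 0:50]
    disc = (rr - 25) ** 2 + (cc - 25) ** 2 <= 15**2
    img = np.where(disc, 40.0, 200.0) + gen.normal(0, 2, size=(50, 50))
    return GrayImage(np.clip(img, 0, 255)), BinaryMask(disc)


@pytest.fixture
def three_plateau():
    """90x30 image with three horizontal constant bands 30 / 120 / 220."""
    img = np.empty((90, 30))
    img[:30] = 30.0
    img[30:60] = 120.0
    img[60:] = 220.0
    return GrayImage(img)
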
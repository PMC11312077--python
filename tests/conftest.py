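import numpy as np
import pytest

from lipidquant.image import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_gray(pixels, mpp=0.2):
    """Wrap a raw array as a calibrated GrayImage."""
    return GrayImage(np.asarray(pixels, dtype=float), mpp)


@pytest.fixture
def disk_image():
    """Noise-free binary image with three disjoint disks of known diameters
    (10, 20, 30 px) at 0.2 µm/px."""
    from skimage.draw import disk

    canvas = np.zeros((256, 256))
    truth = [((60.0, 60.0), 10.0), ((60.0, 190.0), 20.0), ((180.0, 120.0), 30.0)]
    for (r, c), d in truth:
        rr, cc = disk((r, c), d / 2.0, shape=canvas.shape)
        canvas[rr, cc] = 1.0
    return as_gray(canvas), truth
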
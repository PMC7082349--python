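import numpy as np
import pytest

from radepi.volume import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipsoid_study(rng):
    """A small textured ellipsoid phantom: (volume, mask, ac) on a 24^3 grid."""
    shape = (24, 24, 24)
    x, y, z = np.indices(shape)
    c = (12, 10, 13)
    mask = ((x - c[0]) ** 2 / 36 + (y - c[1]) ** 2 / 25 + (z - c[2]) ** 2 / 16) <= 1.0
    vol = np.where(mask, 100 + 8 * rng.normal(size=shape), 20.0)
    vol += 0.5 * rng.normal(size=shape)
    volume = ImageVolume(vol, (1.0, 1.0, 2.0))
    return volume, RoiMask(mask), np.array([11.5, 11.5, 23.0])


def random_quantized_roi(rng, shape=(4, 4, 4), n_levels=4, p_roi=0.8):
    """Random small quantized ROI: levels in 1..n_levels, 0 outside."""
    levels = rng.integers(1, n_levels + 1, size=shape)
    roi = rng.random(shape) < p_roi
    if not roi.any():
        roi[0, 0, 0] = True
    return np.where(roi, levels, 0).astype(np.int64)
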
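import numpy as np
import pytest

from pkdrad.imaging import ROI, CTVolume, SegmentationMask
from pkdrad.phantom import PhantomParams

# small grid keeps phantom generation + feature extraction fast in tests
SMALL_PHANTOM = PhantomParams(shape=(24, 48, 48), semi_axes_mm=(14.0, 12.0, 8.0), n_cysts=12)


@pytest.fixture
def small_phantom_params() -> PhantomParams:
    return SMALL_PHANTOM


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume_mask(rng):
    """A random HU volume with a random nonempty mask on the same grid."""
    shape = (4, 6, 5)
    vol = CTVolume(intensities=rng.normal(40, 12, shape), spacing=(1.5, 1.0, 1.0))
    labels = rng.random(shape) < 0.4
    labels[0, 0, 0] = True  # guarantee nonempty
    mask = SegmentationMask(labels=labels, side="union", spacing=(1.5, 1.0, 1.0))
    return vol, mask


def make_roi(values_3d: np.ndarray, inside: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> ROI:
    coords = np.argwhere(inside)
    return ROI(coordinates=coords, values=np.asarray(values_3d)[inside], spacing=spacing)
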
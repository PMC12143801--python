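import numpy as np
import pytest

from la_cycle.imaging_io import BinaryMask, ImageVolume, IntensityState
from la_cycle.phantom import PhantomConfig, make_phase_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def float64_engine():
    """Run the autograd engine in float64 for tight numeric checks."""
    import la_cycle.nn.autograd as ag
    old = ag.DTYPE
    ag.DTYPE = np.float64
    yield
    ag.DTYPE = old


def make_sphere_mask(shape=(24, 24, 24), radius_mm=8.0,
                     spacing=(1.0, 1.0, 1.0), center=None) -> BinaryMask:
    sp = np.asarray(spacing)
    center = (np.asarray(shape) - 1) / 2.0 * sp if center is None \
        else np.asarray(center)
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, sp)),
                        indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return BinaryMask(voxels=d2 <= radius_mm ** 2, spacing=tuple(spacing))


def tiny_phantom_config(seed=0, vscale=1.0, snr=8.0) -> PhantomConfig:
    """32^3 phantom series small enough for network training tests."""
    program = tuple(2.2 * vscale + 0.3 * np.sin(np.arange(10)))
    return PhantomConfig(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                         atrium_semiaxes=(9.0, 7.5, 7.0),
                         appendage_semiaxes=(4.0, 3.0, 3.0),
                         volume_program=program, target_snr=snr, seed=seed)


def tiny_training_pair(seed=0, vscale=1.0, snr=8.0):
    """One normalized (image, mask) pair drawn from a tiny phantom series."""
    from la_cycle.imaging_io import clip_and_normalize
    img, mask = make_phase_series(tiny_phantom_config(seed, vscale, snr))[seed % 10]
    return clip_and_normalize(img), mask


@pytest.fixture
def random_volume(rng):
    return ImageVolume(voxels=rng.normal(100.0, 50.0, size=(16, 16, 16)),
                       spacing=(0.45, 0.45, 1.0),
                       intensity_state=IntensityState.RAW_HU)
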
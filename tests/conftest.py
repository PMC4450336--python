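"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from shrinkreg.grid import VolumeImage
from shrinkreg.phantom import PhantomSpec, make_head_phantom


@pytest.fixture(scope="session")
def head_phantom():
    """The standard 96×96×40 head phantom at 2×2×3 mm (seed 0)."""
    return make_head_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_smooth_image():
    """A small textured image with smooth multi-scale structure, suitable
    for fast registration tests (24×32×32 voxels at 3×2×2 mm)."""
    from scipy import ndimage

    rng = np.random.default_rng(11)
    shape = (24, 32, 32)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), (2.5, 4, 4), mode="wrap")
    tex *= 100.0 / tex.std()
    z, y, x = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    blob = 300.0 * np.exp(-(((z - 12) / 6) ** 2 + ((y - 16) / 8) ** 2 + ((x - 16) / 8) ** 2))
    return VolumeImage(40.0 + tex + blob, (3.0, 2.0, 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
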
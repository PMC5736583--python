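import numpy as np
import pytest
from scipy import ndimage as ndi


@pytest.fixture(scope="session")
def textured_ball():
    """Textured spherical volume: Gaussian envelope × smooth noise.

    Texture gives the optical-flow data term support everywhere on the
    object (a plain Gaussian has no signal tangential to its level sets).
    """
    shape = (48, 48, 48)
    rng = np.random.default_rng(1)
    noise = ndi.gaussian_filter(rng.normal(size=shape), 2.0)
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    c = [(s - 1) / 2 for s in shape]
    env = np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
                 / (2 * 10**2))
    return env * (1 + 0.5 * noise)


def shift_volume(vol, dxyz):
    """Shift by (dx, dy, dz) with cubic interpolation (array is z,y,x)."""
    dx, dy, dz = dxyz
    return ndi.shift(vol, (dz, dy, dx), order=3, mode="nearest")


@pytest.fixture(scope="session")
def cylinder_volume():
    """Bright cylinder along +z anchored near z=0 (fiber phantom)."""
    vol = np.zeros((60, 32, 32))
    z, y, x = np.mgrid[:60, :32, :32].astype(float)
    vol = np.exp(-((x - 16) ** 2 + (y - 16) ** 2) / (2 * 3**2)) \
        * (z > 4) * (z < 55)
    return vol
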
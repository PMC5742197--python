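import numpy as np
import pytest

from vascatlas.phantom import PhantomParams, make_phantom
from vascatlas.stack import BinaryVolume


@pytest.fixture(scope="session")
def default_scene():
    """One default whole-brain-style phantom shared across read-only tests."""
    return make_phantom(PhantomParams(seed=42))


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free phantom: exact intensities for threshold/growing oracles."""
    return make_phantom(PhantomParams(seed=7, tissue_sd=0.0))


def digital_cylinder(radius_vox: int, length: int = 80, axis_margin: int = 4):
    """Binary digital cylinder along z: in-plane centers within `radius_vox`."""
    n = 2 * radius_vox + 2 * axis_margin + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    vol = np.broadcast_to(disc, (length, n, n)).copy()
    return BinaryVolume(vol, (1.0, 1.0, 1.0), "vessel_mask"), c


@pytest.fixture
def cylinder_factory():
    return digital_cylinder
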
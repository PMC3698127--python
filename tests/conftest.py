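import numpy as np
import pytest

from sparsect.geometry import VolumeImage, make_geometry
from sparsect.phantom import PhantomConfig, make_vessel_phantom


@pytest.fixture(scope="session")
def small_geometry():
    """8 views, 24 detector pixels: small enough for the dense oracle."""
    return make_geometry(8, detector_count=24)


@pytest.fixture(scope="session")
def random_volume():
    rng = np.random.default_rng(42)
    return VolumeImage(rng.random((16, 16)), 0.1)


@pytest.fixture(scope="session")
def default_phantom():
    """The desk-scale arch phantom (192^2, 0.1 mm pitch, 1.2 mm vessel)."""
    return make_vessel_phantom(PhantomConfig(), seed=1)


@pytest.fixture(scope="session")
def small_phantom():
    """A 64^2 arch for fast reconstruction tests."""
    cfg = PhantomConfig(shape=(64, 64), arch_radius=1.5, tube_radius=0.45,
                        arch_center=(0.0, -0.5), bone_center=(0.0, -2.2),
                        bone_radius=0.5)
    return make_vessel_phantom(cfg, seed=1)
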
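import numpy as np
import pytest

import usvolren as u


@pytest.fixture(scope="session")
def const_vol():
    """Homogeneous medium: constant intensity 0.5, 16^3, 1 mm voxels."""
    return u.ScalarVolume(np.full((16, 16, 16), 0.5))


@pytest.fixture(scope="session")
def uniform_tf():
    """Constant optics: tau_t = 1 /mm, albedo 0.5, white."""
    return u.TransferFunction.uniform(extinction=1.0, albedo=0.5)


@pytest.fixture(scope="session")
def ramp_tf():
    """Linear ramp: vacuum at intensity 0 to tau_t = 4, albedo 0.5 at 1."""
    return u.TransferFunction([(0.0, (1.0, 1.0, 1.0), 0.0, 0.5),
                               (1.0, (1.0, 1.0, 1.0), 4.0, 0.5)])


@pytest.fixture(scope="session")
def vacuum_vol():
    return u.ScalarVolume(np.zeros((16, 16, 16)))


@pytest.fixture(scope="session")
def small_phantom():
    """Speckled single-ellipsoid phantom used across modules."""
    spec = u.PhantomSpec(
        dims=(32, 32, 32),
        bodies=[u.Ellipsoid(center=(15.5, 15.5, 15.5),
                            semi_axes=(10.0, 8.0, 8.0), intensity=0.8)],
        background=0.1, speckle_sigma=0.2, seed=11)
    return u.generate_phantom(spec)


@pytest.fixture
def camera16():
    """Head-on view of the 16^3 unit-spacing volumes."""
    return u.Camera(eye=(7.5, -60.0, 7.5), look_at=(7.5, 7.5, 7.5),
                    vfov=20.0, width=16, height=16)
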
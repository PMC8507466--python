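import numpy as np
import pytest

from spectsip.core import Volume
from spectsip.phantoms import Ellipsoid, PhantomSpec
from spectsip.projector import AcquisitionGeometry, SystemModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_geometry():
    """16-cube, 8-view orbit used by the operator-level tests."""
    return AcquisitionGeometry(n_angles=8, matrix_size=16, pixel_size_mm=4.42)


@pytest.fixture
def small_attenuation():
    mu = np.zeros((16, 16, 16))
    mu[4:12, 4:12, 4:12] = 0.0127
    return Volume(mu, 4.42, "attenuation")


@pytest.fixture
def small_model(small_geometry):
    return SystemModel(geometry=small_geometry)


@pytest.fixture
def ideal_model(small_geometry):
    """Delta PSF, no attenuation, no scatter: unweighted ray sums."""
    return SystemModel(
        geometry=small_geometry,
        psf_sigma0_mm=0.0,
        psf_slope=0.0,
        attenuation_enabled=False,
    )


@pytest.fixture
def small_phantom_spec():
    return PhantomSpec(
        grid_size=32,
        body=Ellipsoid((0.0, 0.0, 0.0), (60.0, 45.0, 55.0)),
        lesions=[],
        seed=7,
    )
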
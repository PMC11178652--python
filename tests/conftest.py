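import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hsi_tta.optics import CameraModel, ChromophoreTable, camera_grid, simulation_grid
from hsi_tta import spectral_db

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return ChromophoreTable.default()


@pytest.fixture(scope="session")
def cam():
    return CameraModel()


@pytest.fixture(scope="session")
def sim_grid():
    return simulation_grid()


@pytest.fixture(scope="session")
def cam_grid_():
    return camera_grid()


@pytest.fixture(scope="session")
def small_db():
    """2,000-record database shared across tests that need realistic spectra."""
    return spectral_db.build_database(n=2000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
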
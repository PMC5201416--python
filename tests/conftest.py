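import numpy as np
import pytest

from il2field.doseresponse import default_profiles
from il2field.spatial import Geometry, ModelParams


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale tissue for solver mechanics tests."""
    return Geometry(domain_radius=100.0, n_cells=60, treg_fraction=0.15, dx=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
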
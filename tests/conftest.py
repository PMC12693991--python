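import numpy as np
import pytest

from magthr.config import reference_magnet
from magthr.kinematics import GeometryConfig, calibrate_geometry, state_grid
from magthr.pipeline import NEUTRAL_FIELD_UT
from magthr.statespace import build_dataset


@pytest.fixture(scope="session")
def magnet():
    return reference_magnet()


@pytest.fixture(scope="session")
def geometry(magnet):
    """Reference build geometry with the magnet offset calibrated."""
    return calibrate_geometry(GeometryConfig(), magnet, NEUTRAL_FIELD_UT)


@pytest.fixture(scope="session")
def grid_dataset(geometry, magnet):
    """Noiseless 23,760-state reference dataset on the full grid."""
    return build_dataset(geometry, magnet, state_grid())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
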
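import numpy as np
import pytest

from layermet.config import ImagingConfig, SimulationParams
from layermet.redox import CalibrationModel
from layermet.synthetic import simulate_monolayer


@pytest.fixture(scope="session")
def imaging():
    return ImagingConfig()


@pytest.fixture(scope="session")
def calib():
    return CalibrationModel()


@pytest.fixture(scope="session")
def small_params():
    """Compact expanding strip used by most rendering tests."""
    return SimulationParams(
        domain_um=(600.0, 100.0), n_cells=150, n_frames=4, front_x0_um=420.0)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return simulate_monolayer(small_params, seed=11)


def stamp_blobs(shape, centers, amplitude=100.0, sigma=3.0):
    """Render Gaussian blobs; shared fixture helper."""
    from layermet.synthetic import _stamp_gaussians

    centers = np.asarray(centers, dtype=float)
    return _stamp_gaussians(shape, centers, np.full(len(centers), amplitude), sigma)
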
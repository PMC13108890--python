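import numpy as np
import pytest

from ehtsim.cells import CellParams, load_calibration


@pytest.fixture(scope="session")
def calibration():
    """Shipped default calibration (region -> CellParams)."""
    return load_calibration()


@pytest.fixture(scope="session")
def fast_params():
    """Uncalibrated but well-behaved kinetics for cheap unit tests."""
    return CellParams(tau_in=0.1, tau_out=3.0, tau_close=90.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
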
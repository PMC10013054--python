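import numpy as np
import pytest

from musicbrain.connectome import generate_synthetic_connectome
from musicbrain.fhn import FHNParameters, natural_frequency
from musicbrain.synchrony import DynamicalPhaseMap


@pytest.fixture(scope="session")
def params():
    return FHNParameters()


@pytest.fixture(scope="session")
def natural(params):
    """Measured (omega, T) of the uncoupled oscillator, shared by all tests."""
    return natural_frequency(params)


@pytest.fixture(scope="session")
def phase_map(params):
    return DynamicalPhaseMap(params)


@pytest.fixture(scope="session")
def connectome():
    return generate_synthetic_connectome(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
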
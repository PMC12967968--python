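import numpy as np
import pytest

from neutroscore import BandThresholds, ModelParameters, simulate_cohort


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def bands():
    return BandThresholds()


@pytest.fixture(scope="session")
def cohort():
    """One default 3x20 cohort on a fixed seed, shared across tests."""
    return simulate_cohort(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
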
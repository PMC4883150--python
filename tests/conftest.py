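import numpy as np
import pytest

from gcconnbench import simulate_model1, simulate_model2
from gcconnbench.spectral_measures import FrequencyGrid


@pytest.fixture(scope="session")
def model1_long():
    """One long Model 1 record for consistency / recovery checks."""
    return simulate_model1(50000, seed=101)


@pytest.fixture(scope="session")
def model2_long():
    """One long Model 2 record for consistency / recovery checks."""
    return simulate_model2(50000, seed=102)


@pytest.fixture(scope="session")
def grid32():
    return FrequencyGrid.uniform(32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
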
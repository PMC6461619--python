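import numpy as np
import pytest

from rubberfit.synthetic import default_scenario, realize_scenario


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def realization(scenario):
    return realize_scenario(scenario)


@pytest.fixture(scope="session")
def truth_params(scenario):
    return scenario.true_params


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
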
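import pytest

import refband as rb
from refband.designs import DesignSpec, make_grid, realize_design


@pytest.fixture(scope="session")
def grid_I():
    return make_grid("I")


@pytest.fixture(scope="session")
def grid_II():
    return make_grid("II")


@pytest.fixture(scope="session")
def truth_II_gauss():
    return rb.scenario_truth("II", "gaussian")


@pytest.fixture(scope="session")
def truth_I_gauss():
    return rb.scenario_truth("I", "gaussian")


def uniform_design(n, grid):
    return realize_design(DesignSpec(n=n, a_star=1, b_star=1, grid=grid))


@pytest.fixture(scope="session")
def simulated_sample_II(truth_II_gauss, grid_II):
    """One fixed Scenario II sample of n=2000 for reuse across tests."""
    ages = uniform_design(2000, grid_II)
    return rb.simulate_sample(ages, truth_II_gauss, seed=20240)
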
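import numpy as np
import pytest

import extrapsim as ex


@pytest.fixture(scope="session")
def generation_law():
    return ex.fixture_law("generation")


@pytest.fixture(scope="session")
def analysis_law():
    return ex.fixture_law("analysis")


@pytest.fixture(scope="session")
def scenario1_population(generation_law):
    """One shared 50,000-individual scenario-1 population."""
    return ex.simulate_population(ex.make_scenario(1), generation_law,
                                  n=50_000, seed=11)


@pytest.fixture(scope="session")
def scenario1_estimands(scenario1_population):
    return ex.compute_estimands(scenario1_population)


@pytest.fixture(scope="session")
def nogpm_population():
    """Scenario 1 with the background hazard switched off.

    Every subject progresses and dies of the disease; PF times are exactly
    exponential(0.5) and PD sojourns exactly exponential(0.2).
    """
    return ex.simulate_population(ex.make_scenario(1), ex.zero_law(),
                                  n=50_000, seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
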
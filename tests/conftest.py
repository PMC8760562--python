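import numpy as np
import pytest

from lifebias import ScenarioConfig, build_schedule, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def config1():
    return ScenarioConfig(scenario_id=1)


@pytest.fixture(scope="session")
def schedule1(config1):
    return build_schedule(config1)


@pytest.fixture
def pop1(config1, schedule1):
    """One scenario-1 population at a fixed seed."""
    return simulate_population(schedule1, config1, np.random.default_rng(42))
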
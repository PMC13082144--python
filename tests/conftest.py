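import numpy as np
import pytest

from majic.synthetic import scenario_library


@pytest.fixture(scope="session")
def scenarios():
    return scenario_library()


@pytest.fixture(scope="session")
def rich_sim(scenarios):
    """Noiseless ambulation-like simulation, 10 s at 100 Hz."""
    return scenarios["rich_gait"].simulate(noiseless=True, duration=10.0)


@pytest.fixture(scope="session")
def rich_sim_noisy(scenarios):
    """Noisy ambulation-like simulation, 10 s at 100 Hz."""
    return scenarios["rich_gait"].simulate(duration=10.0)


@pytest.fixture(scope="session")
def quasi_sim_noisy(scenarios):
    """Noisy quasi-static simulation, 10 s at 100 Hz."""
    return scenarios["quasi_static"].simulate(duration=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
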
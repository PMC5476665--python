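import numpy as np
import pytest

from swayabc import ControlParams, PendulumPlant, simulate_sway
from swayabc.experiments import DEFAULT_PARAMS, DEFAULT_PLANT


@pytest.fixture(scope="session")
def default_plant():
    return DEFAULT_PLANT


@pytest.fixture(scope="session")
def default_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def default_trials(default_plant, default_params):
    """Three 60-s trials at the model's default parameters."""
    return simulate_sway(default_plant, default_params, duration=60.0,
                         seed=123, n_trials=3)


@pytest.fixture(scope="session")
def fig_subject():
    """A known single subject: plant, true parameters, three trials."""
    plant = PendulumPlant(m=80.0, h=0.78)
    params = ControlParams(P=128.0, D=37.0, delta=0.16, sigma=0.16, c_on=0.75)
    trials = simulate_sway(plant, params, duration=60.0, seed=42, n_trials=3)
    return plant, params, trials


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
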
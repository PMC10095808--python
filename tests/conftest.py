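import numpy as np
import pytest

from rootniche.defaults import (
    default_parameter_set,
    default_repressorx_scenario,
    default_wt_scenario,
)
from rootniche.model import build_model
from rootniche.simulate import simulate


@pytest.fixture(scope="session")
def wt_scenario():
    """Reference wild-type configuration (canonical tables, fitted schedules)."""
    return default_wt_scenario()


@pytest.fixture(scope="session")
def x_scenario():
    """Reference repressor-X configuration (re-estimated parameters)."""
    return default_repressorx_scenario()


@pytest.fixture(scope="session")
def wt_model(wt_scenario):
    return wt_scenario.model


@pytest.fixture(scope="session")
def wt_hybrid_trajectory(wt_scenario):
    """Wild-type hybrid run with division events."""
    sc = wt_scenario
    return simulate(sc.model, sc.init, (96.0, 144.0), sc.rules)


@pytest.fixture(scope="session")
def x_hybrid_trajectory(x_scenario):
    sc = x_scenario
    return simulate(sc.model, sc.init, (96.0, 144.0), sc.rules)


@pytest.fixture(scope="session")
def default_params():
    return default_parameter_set()


@pytest.fixture()
def plain_wt_model(default_params):
    """WT model with constant (unfitted) production schedules."""
    return build_model("wt", default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
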
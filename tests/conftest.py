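import numpy as np
import pytest

from ipsccm import Model, StimulusSpec, simulate
from ipsccm.protocols import control_state


@pytest.fixture(scope="session")
def control_model():
    return Model()


@pytest.fixture(scope="session")
def steady_state(control_model):
    """Packaged control 1 Hz paced steady-state vector."""
    return control_state(control_model)


@pytest.fixture(scope="session")
def paced_trace(control_model, steady_state):
    """30 s of 1 Hz pacing from steady state, last 8 s recorded."""
    return simulate(control_model, StimulusSpec(mode="paced", frequency=1.0),
                    duration=30.0, record_last=8.0, y0=steady_state.copy())


@pytest.fixture(scope="session")
def spont_trace(control_model, steady_state):
    """40 s free-running from steady state, last 15 s recorded."""
    return simulate(control_model, StimulusSpec(mode="spontaneous"),
                    duration=40.0, record_last=15.0, y0=steady_state.copy())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
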
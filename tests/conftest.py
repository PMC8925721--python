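import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gapasym import (
    NetworkModel,
    SimulationConfig,
    make_single_compartment_trn,
    make_three_compartment_trn,
    simulate,
)


@pytest.fixture(scope="session")
def single_cell():
    return make_single_compartment_trn()


@pytest.fixture(scope="session")
def three_cell():
    return make_three_compartment_trn()


@pytest.fixture(scope="session", autouse=True)
def _warm_compile(single_cell):
    """One tiny run so jit compilation cost is paid once, up front."""
    model = NetworkModel(cells=[single_cell])
    simulate(model, SimulationConfig(dt=0.05, duration=1.0, settle_time=1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220311)
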
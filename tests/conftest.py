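import numpy as np
import pytest

from knotloop.params import ModelParams, RunProtocol
from knotloop.engine import initial_conformation


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams(n_beads=10)


@pytest.fixture()
def jittered_chain():
    """A 10-bead chain with both sticky pairs and bent, jittered geometry.

    Used for brute-force energy/force oracles; the jitter keeps all bonds
    well inside the FENE range.
    """
    params = ModelParams.chain(10, regime="S", internal_pair=(3, 6))
    protocol = RunProtocol(seed=7)
    rng = np.random.default_rng(7)
    state = initial_conformation(params, protocol, rng)
    state.positions += rng.normal(0.0, 0.05, state.positions.shape)
    return state, params


@pytest.fixture(scope="session")
def quick_protocol() -> RunProtocol:
    return RunProtocol(dt=0.005, gamma=0.1, max_steps=5_000_000)
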
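import numpy as np
import pytest

from epinetsim import AdjacencyNetwork, ModelParams, assign_modes, generate_ws_network


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def fast_params():
    """Shorter run for tests that only need the dynamics machinery."""
    return ModelParams(t_total=20.0)


@pytest.fixture(scope="session")
def ws50():
    return generate_ws_network(50, 2, 0.5, seed=100)


@pytest.fixture(scope="session")
def stim_modes(ws50):
    return assign_modes(ws50, "stimulation")


@pytest.fixture(scope="session")
def surgery_modes(ws50):
    return assign_modes(ws50, "surgery")


@pytest.fixture()
def single_node():
    return AdjacencyNetwork(np.zeros((1, 1), dtype=np.int8))
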
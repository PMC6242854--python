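import numpy as np
import pytest

from depclog import AdhesionParams, ChannelNetwork, FieldModel, generate_population


@pytest.fixture(scope="session")
def adhesion():
    return AdhesionParams()


@pytest.fixture(scope="session")
def field_20v():
    return FieldModel(voltage_amplitude=20.0, frequency=1e3)


@pytest.fixture(scope="session")
def network():
    return ChannelNetwork()


@pytest.fixture(scope="session")
def small_network():
    """A 10-branch network for fast transport tests."""
    return ChannelNetwork(n_branches=10)


@pytest.fixture()
def tiny_population(network):
    return generate_population(25.0, volume_ul=1e-3, seed=7, max_cells=400)


@pytest.fixture(scope="session")
def h_grid():
    return np.logspace(-12, -7, 200)
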
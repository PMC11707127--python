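import numpy as np
import pytest

from switchnet.core import NodeTimeSeries
from switchnet.network import LayerStack
from switchnet.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A desk-scale simulation config: 12 nodes, 60 windows of width 20."""
    return SimulationConfig(n_nodes=12, n_frames=79, n_per_group=3,
                            n_subnetworks=4, n_modules=4, seed=7)


@pytest.fixture
def noise_series(rng):
    return NodeTimeSeries(values=rng.standard_normal((6, 120)), tr_seconds=2.0)


def random_stack(rng, n_nodes, n_layers):
    """Random nonnegative symmetric zero-diagonal layer stack."""
    layers = rng.random((n_layers, n_nodes, n_nodes))
    layers = (layers + layers.transpose(0, 2, 1)) / 2
    for layer in layers:
        np.fill_diagonal(layer, 0.0)
    return LayerStack(layers=layers)


@pytest.fixture
def planted_stack():
    """Two disconnected 6-node blocks, identical across 5 layers."""
    n, L = 12, 5
    A = np.zeros((n, n))
    A[:6, :6] = 0.8
    A[6:, 6:] = 0.8
    np.fill_diagonal(A, 0.0)
    return LayerStack(layers=np.repeat(A[None], L, axis=0))
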
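import numpy as np
import pytest

from pcnet.network import LayerSpec, NetworkSpec, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mlp():
    """3-layer ReLU MLP, 6-5-4-3, with seeded parameters."""
    spec = NetworkSpec((
        LayerSpec("affine", (6,), (5,), "relu"),
        LayerSpec("affine", (5,), (4,), "relu"),
        LayerSpec("affine", (4,), (3,), "identity"),
    ))
    return spec, init_params(spec, seed=7)


@pytest.fixture
def scalar_chain():
    """Two-layer scalar linear chain with hand-settable weights."""
    spec = NetworkSpec((
        LayerSpec("affine", (1,), (1,), "identity"),
        LayerSpec("affine", (1,), (1,), "identity"),
    ))
    params = [
        {"W": np.array([[1.5]]), "b": np.zeros(1)},
        {"W": np.array([[0.8]]), "b": np.zeros(1)},
    ]
    return spec, params
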
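import numpy as np
import pytest

from mvcvib import AbundanceTable, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """2 samples × 3 taxa with the values written in the docstring examples."""
    return AbundanceTable(("s1", "s2"), ("f1", "f2", "f3"),
                          np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 4.0]]))


@pytest.fixture
def small_config():
    """A scaled-down model that exercises every architectural component."""
    return ModelConfig(latent_dim=8, hidden_sizes=(16, 12, 12),
                       conv_channels=2, dropout_p=0.0, beta=1e-4,
                       max_epochs=30, patience=5, seed=7)
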
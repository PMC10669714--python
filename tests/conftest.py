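import numpy as np
import pytest

from confrna.conf_model import ModelConfig, small_config
from confrna.synthetic_data import easy_four_family_config, generate


@pytest.fixture(scope="session")
def easy_dataset():
    """800 records, 4 strongly separable synthetic families."""
    return generate(easy_four_family_config(seed=7))


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 records, 4 families — enough for fast protocol tests."""
    return generate(easy_four_family_config(seed=11, n_per_family=30))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def micro_cfg():
    """A gradient-check-sized architecture (window 8, d_model 8)."""
    return ModelConfig(
        max_len=8,
        k=1,
        embedding_dim=4,
        lstm_hidden=2,
        cnn_filters=4,
        cnn_kernels=(3, 3),
        block_kernels=(3, 2, 3),
        block_dilations=(1, 2, 2),
        n_heads=2,
        n_classes=3,
        mlp_hidden=4,
    )
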
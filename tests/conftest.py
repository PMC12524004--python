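import numpy as np
import pytest

from plm2mol.codec import build_default_vocabulary
from plm2mol.decoder import DecoderConfig, init_parameters
from plm2mol.fixtures import make_family_library


@pytest.fixture(scope="session")
def vocab():
    return build_default_vocabulary()


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest config exercising every architectural feature."""
    return DecoderConfig(
        n_layers=2,
        n_heads=2,
        d_model=8,
        seq_len=6,
        vocab_size=7,
        ffn_dim=16,
        dropout=0.0,
        epochs=5,
        batch_size=4,
        learning_rate=0.01,
    )


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_parameters(tiny_config, seed=7)


@pytest.fixture(scope="session")
def small_library():
    return make_family_library(n_families=3, n_per_family=30, seed=11)
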
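import numpy as np
import pytest

from birdsep.config import ModelConfig
from birdsep.dataset import build_dataset
from birdsep.model import SeparationModel
from birdsep.synth import generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small architecture used throughout the unit tests (fast on one CPU)."""
    return ModelConfig(sep_dim=32, n_blocks=2, chunk_len=50, n_filters=64)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return SeparationModel(tiny_cfg, seed=3)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(n_species=4, calls_per_species=4, rate=16000, seed=11)


@pytest.fixture(scope="session")
def small_examples(small_corpus):
    _, examples = build_dataset(small_corpus, 12, noise_snr_range=None, seed=12)
    return examples
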
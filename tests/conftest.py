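import numpy as np
import pytest

from svbreak.model import ModelConfig
from svbreak.simulate import SimConfig, simulate_dataset


def tiny_model_config(**kw) -> ModelConfig:
    """Smallest legal architecture, for fast training in tests."""
    defaults = dict(window=8, conv_channels=(2, 4, 4, 4, 4), fc_sizes=(8, 4))
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One 200 kb simulated dataset shared by read-level tests."""
    cfg = SimConfig(genome_len=200_000, n_per_type=4, coverage=30, seed=101)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free small dataset for exactness (string-level) checks."""
    cfg = SimConfig(genome_len=100_000, n_per_type=2, coverage=20,
                    base_error=0.0, seed=77)
    return simulate_dataset(cfg)
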
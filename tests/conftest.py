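import numpy as np
import pytest

from wheatyield.dataset import split_dataset
from wheatyield.model import ModelConfig
from wheatyield.synthetic import SimConfig, generate_dataset
from wheatyield.training import TrainConfig


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but non-trivial dataset: 6 regions x 7 years = 42 records."""
    cfg = SimConfig(n_regions=6, year_start=2016, year_end=2022, seed=3)
    records, coefs = generate_dataset(cfg)
    return cfg, records, coefs


@pytest.fixture(scope="session")
def tiny_split(tiny_sim):
    _, records, _ = tiny_sim
    return split_dataset(records, {2021, 2022}, seed=0)


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(n_regions=6, d_model=8, d_attn=8, n_heads=2,
                       ffn_dim=16, fan_dp=4, fan_dpbar=8, seed=0)


@pytest.fixture
def fast_train_cfg():
    return TrainConfig(lr=1e-3, batch=16, max_epochs=2, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
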
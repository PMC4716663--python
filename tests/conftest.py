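import copy

import numpy as np
import pytest

from grandloop.config import (
    DopamineConfig,
    Layer5Config,
    ModelConfig,
    StriatumConfig,
)
from grandloop.engine import GrandLoopModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_l5_config():
    """A small layer-5 network for fast unit tests."""
    return Layer5Config(N_E=40, N_I=8, N_A=4, p_EE_init=0.2)


def make_small_model_config() -> ModelConfig:
    """A miniature but complete closed-loop configuration."""
    cfg = ModelConfig()
    cfg.layer5 = Layer5Config(N_E=40, N_I=8, N_A=4, p_EE_init=0.2,
                              develop_steps=2000)
    cfg.striatum = StriatumConfig(N_Str=20, N_Cx_Str=5)
    cfg.dopamine = DopamineConfig(N_DA=4, N_Str_DA=5)
    cfg.loop.develop_steps = 2000
    cfg.loop.bias_steps = 200
    cfg.loop.N_Str_Th = 3
    cfg.loop.tau_X = 50
    return cfg


@pytest.fixture
def small_model_config():
    return make_small_model_config()


@pytest.fixture(scope="session")
def ring_model():
    """A full-size model taken through the complete development and
    bias-adjustment schedule, shared across tests.  Tests must deepcopy it
    before stepping or mutating."""
    cfg = ModelConfig()
    model = GrandLoopModel(cfg, seed=7)
    model.develop()
    model.run_phase(cfg.loop.bias_steps, bias_phase=True)
    return model


@pytest.fixture
def ring_model_copy(ring_model):
    return copy.deepcopy(ring_model)
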
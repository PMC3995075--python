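import numpy as np
import pytest

from gravikin.model_core import GrowthProfile, ModelParams


@pytest.fixture
def params_b10_g10() -> ModelParams:
    """B = 10, gamma_tilde = 10, L/R = 100 (convergent regime)."""
    return ModelParams(beta_tilde=1.0, gamma_tilde=10.0, R=1.0, E0=1.0, Lgz=100.0, L0=100.0)


@pytest.fixture
def params_b10_g01() -> ModelParams:
    """B = 10, gamma_tilde = 0.1, L/R = 100 (divergent regime)."""
    return ModelParams(beta_tilde=0.01, gamma_tilde=0.1, R=1.0, E0=1.0, Lgz=100.0, L0=100.0)


@pytest.fixture
def exp_profile() -> GrowthProfile:
    return GrowthProfile(mode="exponential", E0=1.0, Lgz=100.0)


@pytest.fixture
def sub_profile() -> GrowthProfile:
    return GrowthProfile(mode="subapical_step", E0=1.0, Lgz=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
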
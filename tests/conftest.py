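import numpy as np
import pytest

from dynmodal.config import RunConfig
from dynmodal.simulate import GeneratorConfig, generate_dataset


def small_config(**overrides) -> RunConfig:
    """Scaled-down model configuration used throughout the tests."""
    base = dict(
        d_model=12,
        patch_long_len=12, patch_long_stride=12,
        patch_short_len=4, patch_short_stride=2,
        mamba_hidden_dim=24, mamba_state_dim=4, mamba_conv_kernel=4,
        lwt_heads=2, lwt_head_dim=6, lwt_ff_dim=24, lwt_window=5, lwt_layers=1,
        lwt_max_len=64, n_fusion_units=2, cost_lambda=0.01,
        lr=3e-3, batch_size=16, patience=6, max_epochs=20, seed=1,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture
def run_config() -> RunConfig:
    return small_config()


@pytest.fixture
def tiny_samples():
    """Small audio-informative trend dataset (separable at low noise)."""
    cfg = GeneratorConfig(
        n_samples=24, T_a=48, D_a=4, T_v=48, D_v=4,
        trend_strength=1.5, fluctuation_strength=1.0,
        informative_modality="audio", noise_sd=0.3,
        positive_fraction=0.5, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
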
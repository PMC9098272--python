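import numpy as np
import pytest

from midecoder import (BackboneConfig, CropSpec, DSCConvLSTM, ModelConfig,
                       RecurrentSpec, AttentionSpec, SyntheticSpec, generate_dataset)


@pytest.fixture(scope="session")
def tiny_ds():
    """Eight strongly-modulated trials on eight channels (two per class)."""
    spec = SyntheticSpec(n_trials=8, n_classes=4, n_channels=8, erd_depth=0.8,
                         noise_sd=1.0, seed=42)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_model_cfg():
    """A narrow model for fast forward/backward tests (same architecture)."""
    return ModelConfig(
        backbone=BackboneConfig(n_channels=8, f1=4, f2=4, f3=8, f4=8),
        recurrent=RecurrentSpec(hidden_size=8, candidate_kernel=3),
        attention=AttentionSpec(key_dim=4),
        n_classes=4, seed=1)


@pytest.fixture()
def small_model(small_model_cfg):
    return DSCConvLSTM(small_model_cfg)


@pytest.fixture(scope="session")
def coarse_crop():
    """A sparse crop grid (4 windows per trial) for fast pipeline tests."""
    return CropSpec(window_len_s=2.0, start_min_s=-0.5, start_max_s=2.0,
                    stride_samples=200, fs=250.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
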
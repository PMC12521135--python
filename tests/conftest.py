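import numpy as np
import pytest

from ndfusion import CohortConfig, EncoderConfig, ModelConfig, generate_cohort
from ndfusion.synthetic import standardize_tabular, train_feature_stats


@pytest.fixture(scope="session")
def small_encoder_config() -> EncoderConfig:
    """Desk-scale architecture for 8x16x16 volumes."""
    return EncoderConfig(embed_dim=16, image_channels=(4, 8), ssm_token_dim=4,
                         ssm_state_dim=2, groupnorm_groups=2)


@pytest.fixture(scope="session")
def small_model_config(small_encoder_config) -> ModelConfig:
    return ModelConfig(encoder=small_encoder_config)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient multimodal cohort with 8x16x16 volumes."""
    cfg = CohortConfig(n_total=20, n_positive=8, volume_shape=(8, 16, 16),
                       lesion_radius_range=(1.0, 2.0), seed=7)
    records, volumes, labels = generate_cohort(cfg)
    tabular = standardize_tabular(records, train_feature_stats(records))
    return records, volumes, tabular, labels


def finite_difference_grad(fn, param, idx, eps: float = 1e-6) -> float:
    """Central finite difference of scalar ``fn()`` w.r.t. ``param.data[idx]``."""
    orig = param.data[idx]
    param.data[idx] = orig + eps
    up = fn()
    param.data[idx] = orig - eps
    down = fn()
    param.data[idx] = orig
    return (up - down) / (2 * eps)
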
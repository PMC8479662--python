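import numpy as np
import pytest

from bifuse.io import FeatureMatrix, SurvivalRecord
from bifuse.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """4 samples x 3 features, one missing cell."""
    values = np.array(
        [
            [1.0, 4.0, 0.5],
            [2.0, np.nan, 0.7],
            [3.0, 6.0, 0.9],
            [4.0, 8.0, 1.1],
        ]
    )
    return FeatureMatrix(["s1", "s2", "s3", "s4"], ["fa", "fb", "fc"], values, "genomic")


@pytest.fixture
def toy_records():
    return [
        SurvivalRecord("s1", 30.0, 1),
        SurvivalRecord("s2", 80.0, 0),
        SurvivalRecord("s3", 30.0, 0),
        SurvivalRecord("s4", 65.0, 1),
    ]


def tiny_config(**overrides) -> ModelConfig:
    """A miniature architecture for fast unit tests (not the reference sizes)."""
    base = dict(
        variant="full_fusion",
        l=4,
        k=3,
        m=2,
        s=2,
        widths=(8, 4),
        dropout=(0.0, 0.0),
        learning_rate=1e-2,
        epochs=5,
        batch_size=8,
        seed=7,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def small_labelled_cohort():
    """A small separable two-modality dataset for training tests."""
    rng = np.random.default_rng(99)
    n = 64
    g = rng.standard_normal((n, 4))
    p = rng.standard_normal((n, 4))
    y = (g[:, 0] + p[:, 0] > 0).astype(int)
    return g, p, y
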
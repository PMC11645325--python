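import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from edlama.datagen import GeneratorConfig, generate_visits
from edlama.impute import encode_features
from edlama.space import ParamSpec, SearchSpace

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_visits():
    """A 3,000-visit synthetic cohort with the default strong planted signal."""
    table, truth = generate_visits(GeneratorConfig(n=3000, prevalence=0.05, seed=42))
    return table, truth


@pytest.fixture(scope="session")
def encoded_table(small_visits):
    table, _ = small_visits
    return encode_features(table)


@pytest.fixture
def float_axis():
    return SearchSpace((ParamSpec("x", "float", 0.0, 10.0),))


@pytest.fixture
def two_int_axes():
    return SearchSpace(
        (ParamSpec("a", "integer", 1, 5), ParamSpec("b", "integer", 1, 5))
    )


def brute_force_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney AUC with ties counted one half (test oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


@pytest.fixture
def auc_oracle():
    return brute_force_auc


def toy_frame(n=200, d=4, seed=0, signal=2.0):
    """Small labeled frame with one informative column ('f0')."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    p = 1.0 / (1.0 + np.exp(-(signal * X[:, 0])))
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(d)])
    df["label"] = y
    return df


@pytest.fixture
def labeled_frame():
    return toy_frame()
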
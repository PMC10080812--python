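import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pssmstack import (
    BaseConfig,
    FeatureTable,
    ScaledPssm,
    SimulationSpec,
    featurize_batch,
    gen_dataset,
    sigmoid_scale,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_scaled(rng):
    """A 30 x 20 scaled PSSM with entries strictly inside (0, 1)."""
    return ScaledPssm(id="fix30", values=rng.uniform(0.05, 0.95, size=(30, 20)))


@pytest.fixture(scope="session")
def small_dataset():
    """40 labeled synthetic profiles (20 per class) with a strong signal."""
    spec = SimulationSpec(n_pos=20, n_neg=20, length_range=(20, 40), effect_size=2.0, seed=7)
    return gen_dataset(spec)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    profiles, labels = small_dataset
    return featurize_batch([sigmoid_scale(p) for p in profiles], labels)


def fast_configs():
    """Shrunken base learners for tests where hyperparameter scale is
    irrelevant (leakage, determinism, plumbing)."""
    return (
        BaseConfig(
            "lightgbm",
            (
                ("n_estimators", 15),
                ("learning_rate", 0.2),
                ("max_depth", 3),
                ("min_child_samples", 2),
            ),
        ),
        BaseConfig("svm_rbf", (("gamma", 0.05), ("C", 1.0))),
        BaseConfig("extra_trees", (("n_estimators", 10),)),
    )


@pytest.fixture
def signal_noise_table(rng):
    """200 samples: 5 features track the label at effect size 2, 45 are noise."""
    n = 200
    y = np.array([1] * 100 + [0] * 100)
    X = rng.normal(size=(n, 50))
    X[:, :5] += 2.0 * y[:, None]
    names = [f"sig_{j}" for j in range(5)] + [f"noise_{j}" for j in range(45)]
    return FeatureTable(ids=[f"s{i}" for i in range(n)], names=names, values=X, labels=y)
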
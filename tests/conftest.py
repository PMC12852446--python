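import numpy as np
import pytest

from ssmboost import CohortSpec, Dataset, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """20-sample, 3-feature dataset with a clean linear signal."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 3))
    y = (X[:, 0] > 0).astype(int)
    return Dataset(X=X, y=y, feature_names=["a", "b", "c"])


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort reused across slower tests."""
    spec = CohortSpec(n=300, d=12, prevalence=0.4, seed=11)
    return generate_cohort(spec)
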
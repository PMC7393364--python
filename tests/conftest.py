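import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from explspace import (
    SyntheticSpec,
    explain_matrix,
    generate_hypercube_dataset,
    split_supersets,
    train_random_forest,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The default hypercube benchmark: 16 classes, 50 features, 1600 rows."""
    return generate_hypercube_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def default_binary(default_dataset):
    return split_supersets(default_dataset.y_subclass, (0, 1, 2))


@pytest.fixture(scope="session")
def default_model(default_dataset, default_binary):
    model = train_random_forest(default_dataset.X, default_binary, seed=0)
    model.feature_names = list(default_dataset.feature_names)
    return model


@pytest.fixture(scope="session")
def default_explanations(default_model, default_dataset):
    return explain_matrix(default_model, default_dataset.X)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
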
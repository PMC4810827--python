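import numpy as np
import pytest

from foodweb_ergm import FoodWeb, fixture_web
from foodweb_ergm.config_statistics import (
    ConfigurationStatistic,
    ModelSpec,
    statistic_names,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def chain3():
    return fixture_web("chain3")


@pytest.fixture
def omnivory3():
    return fixture_web("omnivory3")


@pytest.fixture
def baltic_like():
    return fixture_web("baltic_like_30")


@pytest.fixture
def full_model_spec():
    """Every registered statistic that may enter a model, lambda = 2."""
    return ModelSpec(
        ConfigurationStatistic(name, 2.0)
        for name in statistic_names(model_only=True)
    )


def random_web(rng, n, density=0.3):
    A = (rng.random((n, n)) < density).astype(np.uint8)
    np.fill_diagonal(A, 0)
    return FoodWeb([f"s{i}" for i in range(n)], A)


@pytest.fixture
def random_web_factory():
    return random_web
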
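import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from npk3414.datasets import (  # noqa: E402
    canonical_trial,
    default_prices,
    published_single_factor_models,
    published_ternary_model,
)


@pytest.fixture(scope="session")
def trial():
    """Canonical trial with published two-decimal treatment means attached."""
    return canonical_trial()


@pytest.fixture(scope="session")
def trial_plot_means():
    """Canonical trial with means recomputed from the integer plot yields."""
    return canonical_trial(means="plots")


@pytest.fixture(scope="session")
def prices():
    return default_prices()


@pytest.fixture(scope="session")
def ternary():
    """The published three-factor effect function."""
    return published_ternary_model()


@pytest.fixture(scope="session")
def singles():
    """The published single-factor effect functions keyed by nutrient."""
    return published_single_factor_models()
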
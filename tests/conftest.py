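import numpy as np
import pytest

from countsim import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A default synthetic 24-observer cohort (study-calibrated targets)."""
    return generate_cohort(CohortParams(seed=42))


@pytest.fixture(scope="session")
def identity_cohort():
    """Two error-free observers: zero margins, zero count noise."""
    params = CohortParams(
        n_observers=2,
        small_group_margin=(0.0, 0.0),
        large_group_margin=(0.0, 0.0),
        residual_sd_range=(0.0, 0.0),
        residual_sd_mean=0.0,
        seed=5,
    )
    return generate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
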
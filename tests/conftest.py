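import numpy as np
import pytest

from slaprvfl import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across the session (n=476)."""
    X, y = generate_cohort(default_cohort_spec(seed=1))
    return X, y


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast fitting tests."""
    X, y = generate_cohort(default_cohort_spec(n=80, seed=2))
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
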
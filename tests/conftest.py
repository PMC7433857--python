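import numpy as np
import pytest

from semloss import default_profiles, load_fixture, simulate_cohort


@pytest.fixture(scope="session")
def fixture28():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_frame(fixture28):
    return fixture28.frame


@pytest.fixture(scope="session")
def small_cohort():
    """30 participants per stock profile, fixed seed."""
    return simulate_cohort([(p, 30) for p in default_profiles()], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
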
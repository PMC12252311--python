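import numpy as np
import pytest

import oxyflux as ox
from oxyflux import preprocess as pp


@pytest.fixture(scope="session")
def cohort():
    """Standard 21-subject synthetic cohort (14 male / 7 female)."""
    return ox.generate_cohort(21, 7)


@pytest.fixture(scope="session")
def cohort_windows(cohort):
    return pp.windows_from_cohort(cohort)


@pytest.fixture(scope="session")
def one_session():
    profile = ox.sample_profile(1, "male", "S01")
    return ox.simulate_session(profile, rng_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
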
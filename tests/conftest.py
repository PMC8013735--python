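import numpy as np
import pytest
from hypothesis import settings

from dfcstates import build_taper, cobre_like_config, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_taper():
    return build_taper(20, 3.0, 2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12+12-subject cohort from the default preset, shared across tests."""
    return generate_cohort(cobre_like_config(n_hc=12, n_sz=12, seed=20240901))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
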
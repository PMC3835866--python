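import numpy as np
import pytest

from sgapaf.growth import make_synthetic_standard
from sgapaf.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def standard():
    return make_synthetic_standard()


@pytest.fixture(scope="session")
def small_cohort(standard):
    """A 2,000-mother synthetic cohort shared by read-only tests."""
    cfg = CohortConfig(n_mothers=2000, seed=11, history_miscount_rate=0.05)
    return generate_cohort(cfg, standard) + (cfg,)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
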
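import numpy as np
import pytest

from ppct.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibrated cohort at the emulated study scale."""
    return generate_cohort(CohortConfig(n_eyes=114, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
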
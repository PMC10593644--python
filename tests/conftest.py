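import numpy as np
import pytest

from dynfnc import CohortConfig, simulate_timecourses


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-subject default-structure cohort shared by read-only tests."""
    config = CohortConfig(n_subjects=4, seed=123)
    tcs, truth = simulate_timecourses(config)
    return config, tcs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
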
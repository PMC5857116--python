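import numpy as np
import pytest

from starmh import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort at generator defaults (no missing)."""
    cohort, truth = simulate_cohort(SimulationConfig(n_persons=185, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for estimator-recovery checks."""
    cohort, truth = simulate_cohort(SimulationConfig(n_persons=1000, seed=11))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
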
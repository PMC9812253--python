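import numpy as np
import pytest

from assr.pipeline import make_fixture
from assr.synthcohort import CohortParams, simulate_subject


@pytest.fixture(scope="session")
def perfect_locking_cohort():
    """Tiny noiseless, perfectly phase-locked cohort (capped kappa)."""
    subjects, params = make_fixture("perfect_locking")
    return subjects, params


@pytest.fixture(scope="session")
def smoke_cohort():
    """Tiny cohort with the default effect sizes."""
    subjects, params = make_fixture("smoke")
    return subjects, params


@pytest.fixture(scope="session")
def one_subject():
    """A single small simulated subject for signal-level tests."""
    params = CohortParams(
        n_subjects=1, trials_range=(20, 20), n_vertices_per_hemisphere=6,
        sample_rate_hz=250.0, seed=42,
    )
    return simulate_subject(params, 0), params


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
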
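import numpy as np
import pytest

from normdev import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with group effects, shared across tests."""
    return generate_cohort(CohortConfig(n_controls=60, n_patients=70, seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose groups are exchangeable (no effect, matched marginals)."""
    return generate_cohort(CohortConfig(n_controls=60, n_patients=70, seed=43).null())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
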
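import warnings

import pytest

from sr2norm import CohortValidationWarning, GenerativeConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized simulated cohort shared by read-only tests."""
    return simulate_cohort(GenerativeConfig(n=60, seed=12345))


@pytest.fixture(scope="session")
def cohort_with_trials():
    cfg = GenerativeConfig(n=8, seed=77)
    return simulate_cohort(cfg, return_trials=True)


@pytest.fixture(autouse=True)
def _no_unrelated_validation_noise():
    """Keep validation warnings visible but non-fatal across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("always", CohortValidationWarning)
        yield
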
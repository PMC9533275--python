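import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_cohort():
    """Synthetic normative cohort at the published sample structure."""
    from telenorms import simulate_healthy_cohort, study_sample_spec

    return simulate_healthy_cohort(study_sample_spec(n=204, seed=1))


@pytest.fixture(scope="session")
def patient_cohort():
    """Simulated clinical cohort (n=100, synthetic stand-in score levels)."""
    from telenorms import amci_patient_spec, simulate_patient_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_patient_cohort(amci_patient_spec(n=100, seed=3))


@pytest.fixture(scope="session")
def published_eqs():
    from telenorms import published_equations

    return published_equations()
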
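import pytest

from burncohort import CohortConfig, build_analysis_frame, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (17 cases + 17 non-cases), fixed seed."""
    return generate_cohort(CohortConfig(), seed=0)


@pytest.fixture(scope="session")
def frame(cohort):
    patients, infections = cohort
    return build_analysis_frame(patients, infections)
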
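import pytest

from musclebone.evaluation import standardized_cohort
from musclebone.synthetic_cohort import CohortConfig, fixture_config, make_fixture


@pytest.fixture(scope="session")
def tiny_table():
    """8 participants x 2 sessions, no missingness, strong paths."""
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def tiny_standardized():
    """Tiny fixture, analysis-ready on the configured standardized scale."""
    return standardized_cohort(fixture_config("tiny"), seed=0)


@pytest.fixture(scope="session")
def study_table():
    """One study-scale cohort (180 participants, 434 observations)."""
    return make_fixture("study_scale", seed=0)


@pytest.fixture(scope="session")
def study_standardized():
    return standardized_cohort(CohortConfig(), seed=0)
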
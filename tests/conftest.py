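import pytest
from hypothesis import settings

from stonekit import study_cohort, study_count_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_counts():
    """Published per-SNP genotype count tables (case, control)."""
    return study_count_fixture()


@pytest.fixture(scope="session")
def cohort():
    """Synthetic 200/200 cohort matching the published margins exactly."""
    return study_cohort(seed=11)
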
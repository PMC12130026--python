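import pytest

from pimscreen.engine import screen_cohort
from pimscreen.fixture import generate_reference_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 450-patient reference cohort (built once)."""
    return generate_reference_fixture()


@pytest.fixture(scope="session")
def fixture_flags(fixture_cohort):
    """Screening result for the reference cohort."""
    return screen_cohort(fixture_cohort)
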
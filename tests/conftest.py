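import pytest

from androgenaxis import classify_cohort
from androgenaxis.synthetic import (
    fixture_group_a,
    fixture_group_b,
    fixture_group_c,
)


@pytest.fixture(scope="session")
def group_c():
    return classify_cohort(fixture_group_c(seed=0))


@pytest.fixture(scope="session")
def group_b():
    return classify_cohort(fixture_group_b(seed=0))


@pytest.fixture(scope="session")
def group_a():
    return classify_cohort(fixture_group_a(seed=0))
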
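import pytest

from epilat.cohort import load_reference_cohort
from epilat.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def reference_cohort():
    """The packaged 48-patient prospective cohort."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1234)


@pytest.fixture(scope="session")
def null_spec():
    """All effects zero: controls and 'cases' share one distribution."""
    return SyntheticSpec(seed=1234).with_effects(0.0)
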
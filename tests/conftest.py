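import pytest

from chanse import default_spec, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """Default-sized synthetic cohort (142 records), fixed seed."""
    return generate_cohort(spec, seed=1)
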
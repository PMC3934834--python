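import pytest

from spireformin import Conditions, default_rate_constants


@pytest.fixture(scope="session")
def rc():
    return default_rate_constants()


@pytest.fixture(scope="session")
def pingpong_cond():
    """The co-presence condition of the single-filament movies."""
    return Conditions(spire_uM=0.010, formin_uM=0.020, pa_uM=1.0)
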
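import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pgpbpk.population import reference_subject  # noqa: E402


@pytest.fixture(scope="session")
def adult():
    return reference_subject("adult")


@pytest.fixture(scope="session")
def neonate():
    return reference_subject("term_neonate")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
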
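import string

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from typability import default_layout, default_resources  # noqa: E402


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def resources():
    return default_resources()


@pytest.fixture(scope="session")
def supported_alphabet(layout):
    """Printable characters every generated test string may use."""
    return "".join(sorted(set(string.ascii_letters + string.digits + " ,.!?';")))
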
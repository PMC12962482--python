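import pytest
from hypothesis import settings

from ipn_cea import default_parameters

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Packaged base-case parameters (treated as immutable)."""
    return default_parameters()
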
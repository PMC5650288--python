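import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("ci")


@pytest.fixture
def quiet():
    """Silence the pipeline's data-quality warnings inside noisy simulations."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
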
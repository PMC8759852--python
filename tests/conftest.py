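import warnings

import pytest
from hypothesis import HealthCheck, settings

from neutroplan import CutLevels, builtin_alamal

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def alamal():
    with warnings.catch_warnings():
        # the published total-budget falsity spreads cross zero by design
        warnings.simplefilter("ignore", UserWarning)
        return builtin_alamal()


@pytest.fixture(scope="session")
def cuts():
    """The cut levels the case study applies to every budget."""
    return CutLevels(alpha=0.1, beta=0.9, gamma=0.8)
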
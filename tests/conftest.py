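import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ofcnet.protocol import SessionProtocol

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def protocol():
    return SessionProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
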
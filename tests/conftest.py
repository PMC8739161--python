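import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phase1pk.core_pk import PKParameters

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def typical_params() -> PKParameters:
    """A mAb-like parameter set: CL 0.216 L/day, Vss 5 L, t1/2 ~ 16 d."""
    return PKParameters(cl=0.009, v1=3.5, q=0.03, v2=1.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
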
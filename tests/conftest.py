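import math

import pytest
from hypothesis import HealthCheck, settings

from elisashift import CurveParams, SimSpec, default_true_params

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def ref_params() -> CurveParams:
    """The published-style reference curve used across fixtures."""
    return default_true_params()


@pytest.fixture
def small_spec() -> SimSpec:
    """Two-batch spec: reference plus one batch shifted by ln 2, noiseless."""
    return SimSpec(batch_shifts={"lot1": 0.0, "lot2": math.log(2.0)},
                   od_noise_sd=0.0, plates_per_batch=1)
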
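import math

import pytest
from hypothesis import HealthCheck, settings

import tdtkit as tdt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fly_curve():
    """A Drosophila-like TDT curve: z = 2.5 °C/decade, sCT_max(1 h) = 40 °C."""
    return tdt.TDTCurve(z=2.5, ct_ref=40.0, t_ref=60.0)


@pytest.fixture
def anchored_truth():
    """The single-point worked example: a curve through (37 °C, 40 min)
    whose slope also puts (41 °C, 1 min) on the line, i.e.
    z = 4 / log10(40) ≈ 2.4968."""
    z = 4.0 / math.log10(40.0)
    ct_ref = 37.0 + z * math.log10(40.0 / 60.0)
    return tdt.TDTCurve(z=z, ct_ref=ct_ref, t_ref=60.0)
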
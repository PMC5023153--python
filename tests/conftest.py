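import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from filmdose.calibration import CalibrationCurve, Channel
from filmdose.simulate import default_lot_curves

# curve fixtures are frozen dataclasses, so sharing them across generated
# inputs is safe
settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def std_curve() -> CalibrationCurve:
    """The reference worked-example curve: X(D) = 0.20 + 40/(D + 50)."""
    return CalibrationCurve(Channel.R, a=0.20, b=40.0, c=-50.0, dose_domain=(0.0, 400.0))


@pytest.fixture
def lot_curves():
    return default_lot_curves()


@st.composite
def valid_curves(draw) -> CalibrationCurve:
    """Random monotone-decreasing standard-form curves with X(0) <= 1."""
    a = draw(st.floats(0.05, 0.5))
    c = draw(st.floats(-300.0, -20.0))
    b_max = (1.0 - a) * (-c)
    b = draw(st.floats(0.2 * b_max, b_max))
    return CalibrationCurve(Channel.R, a=a, b=b, c=c, dose_domain=(0.0, 400.0))


def render_triplet(curves, dose, delta=0.0):
    """Exact (unquantized) response triplet at one dose and disturbance."""
    return np.array(
        [(1.0 + delta) * c._eval_unchecked(np.asarray(float(dose))) for c in curves]
    )
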
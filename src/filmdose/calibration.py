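"""Per-channel dose-response calibration for radiochromic film.

The scanner response of a film lot in one color channel is modeled by a
rational function of dose.  Two equivalent parameterizations are supported:

* ``standard``:    X(D) = a + b / (D - c)
* ``saturating``:  X(D) = A + B * D / (D + C)

Both describe the same three-parameter family (the saturating form equals
``(A+B) + (-B*C) / (D - (-C))``), so fitting is always carried out in the
standard parameterization and converted if required.

``response`` is the dimensionless mean 16-bit pixel value of a region of
interest divided by 65535, a transmission-like quantity in (0, 1] that falls
monotonically with dose for radiochromic film.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DomainError,
    FitRejectedError,
    InsufficientDataError,
    ResponseRangeError,
    SingularityError,
)

__all__ = [
    "Channel",
    "CurveForm",
    "CalibrationCurve",
    "CalibrationPoint",
    "eval_response",
    "invert_response",
    "fit_calibration",
]


class Channel(str, Enum):
    R = "R"
    G = "G"
    B = "B"


class CurveForm(str, Enum):
    STANDARD = "standard"
    SATURATING = "saturating"


@dataclass(frozen=True)
class CalibrationPoint:
    """One measured (dose, response) pair.

    dose is the known delivered dose in cGy; response is the normalized ROI
    mean pixel value in (0, 1].
    """

    dose: float
    response: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if not (0.0 < self.response <= 1.0):
            raise ValueError(
                f"response must be in (0, 1], got {self.response}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Rational dose-response curve of one color channel of one film lot.

    For the standard form the coefficients are (a, b, c) with the pole at
    D = c; for the saturating form they are (A, B, C) with the pole at
    D = -C.  The pole must lie strictly outside ``dose_domain`` and the
    response must be strictly decreasing over the domain (b > 0 with
    c < D_min in the standard form), matching film whose transmission falls
    with dose.
    """

    channel: Channel
    a: float
    b: float
    c: float
    dose_domain: tuple[float, float]
    lot_id: str = ""
    form: CurveForm = CurveForm.STANDARD

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "form", CurveForm(self.form))
        d_min, d_max = self.dose_domain
        if not d_min < d_max:
            raise ValueError(f"empty dose domain {self.dose_domain}")
        pole = self.pole
        if d_min <= pole <= d_max:
            raise FitRejectedError(
                f"pole at D={pole:g} cGy lies inside dose domain "
                f"[{d_min:g}, {d_max:g}]"
            )
        # dX/dD = -b/(D-c)^2 (standard) or B*C/(D+C)^2 (saturating): the sign
        # is constant once the pole is outside the domain; require decreasing.
        slope_sign = -self.b if self.form is CurveForm.STANDARD else self.b * self.c
        if not slope_sign < 0:
            raise FitRejectedError(
                "response must be strictly decreasing over the dose domain"
            )

    @property
    def pole(self) -> float:
        return self.c if self.form is CurveForm.STANDARD else -self.c

    def as_standard(self) -> "CalibrationCurve":
        """Equivalent curve in the standard (a, b, c) parameterization."""
        if self.form is CurveForm.STANDARD:
            return self
        a, b, c = self.a + self.b, -self.b * self.c, -self.c
        return replace(self, a=a, b=b, c=c, form=CurveForm.STANDARD)

    def response_range(self) -> tuple[float, float]:
        """(lowest, highest) achievable response = (X(D_max), X(D_min))."""
        d_min, d_max = self.dose_domain
        return (
            float(self._eval_unchecked(np.asarray(d_max))),
            float(self._eval_unchecked(np.asarray(d_min))),
        )

    def _eval_unchecked(self, dose: np.ndarray) -> np.ndarray:
        if self.form is CurveForm.STANDARD:
            return self.a + self.b / (dose - self.c)
        return self.a + self.b * dose / (dose + self.c)

    def _invert_unchecked(self, response: np.ndarray) -> np.ndarray:
        if self.form is CurveForm.STANDARD:
            return self.c + self.b / (response - self.a)
        return self.c * (response - self.a) / (self.a + self.b - response)


def eval_response(curve: CalibrationCurve, dose: float) -> float:
    """Response X(D) of ``curve`` at ``dose`` (cGy).

    Raises DomainError outside the dose domain and SingularityError at the
    pole (unreachable for a valid curve, kept for defense in depth).
    """
    d_min, d_max = curve.dose_domain
    if not d_min <= dose <= d_max:
        raise DomainError(
            f"dose {dose:g} cGy outside domain [{d_min:g}, {d_max:g}]"
        )
    if dose == curve.pole:
        raise SingularityError(f"dose {dose:g} cGy is the curve pole")
    return float(curve._eval_unchecked(np.asarray(float(dose))))


def invert_response(curve: CalibrationCurve, response: float) -> float:
    """Dose (cGy) at which ``curve`` produces ``response``.

    The closed-form inverse of the rational curve; valid only for responses
    strictly inside the achievable interval (X(D_max), X(D_min)).  Responses
    outside that interval raise ResponseRangeError -- no silent clamping.
    """
    lo, hi = curve.response_range()
    if not lo <= response <= hi:
        raise ResponseRangeError(
            f"response {response:g} outside achievable interval "
            f"[{lo:g}, {hi:g}]"
        )
    return float(curve._invert_unchecked(np.asarray(float(response))))


def _exact_three_point(
    doses: np.ndarray, resps: np.ndarray
) -> tuple[float, float, float]:
    """Solve a + b/(D_i - c) = n_i exactly for three distinct doses.

    Eliminating a and b from the pairwise differences gives a linear
    equation in the pole c; b and a then follow by back-substitution.
    """
    d1, d2, d3 = doses
    n1, n2, n3 = resps
    if np.isclose(n2, n3) or np.isclose(n1, n2):
        raise FitRejectedError("calibration responses are not distinct")
    r = (n1 - n2) / (n2 - n3)
    p = r * (d3 - d2)
    q = d2 - d1
    if np.isclose(p, q):
        raise FitRejectedError("degenerate calibration geometry (pole at infinity)")
    c = (p * d1 - q * d3) / (p - q)
    b = (n1 - n2) * (d1 - c) * (d2 - c) / (d2 - d1)
    a = n1 - b / (d1 - c)
    return float(a), float(b), float(c)


def fit_calibration(
    points: list[CalibrationPoint],
    form: CurveForm | str = CurveForm.STANDARD,
    *,
    channel: Channel | str = Channel.R,
    lot_id: str = "",
    dose_domain: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Least-squares fit of the rational response curve to measured points.

    Requires >= 3 points with distinct doses.  With exactly 3 points the
    exact algebraic solution is returned (zero residual); with more, a
    nonlinear least-squares minimization of the summed squared response
    residuals is run, initialized from the exact solve of the (lowest,
    middle, highest)-dose triple so the result does not depend on a guess.

    ``dose_domain`` defaults to the span of the measured doses.  Fits whose
    pole falls inside the domain or whose response is not strictly
    decreasing are rejected, never silently returned.
    """
    form = CurveForm(form)
    doses = np.array([p.dose for p in points], dtype=float)
    resps = np.array([p.response for p in points], dtype=float)
    order = np.argsort(doses)
    doses, resps = doses[order], resps[order]
    if len(np.unique(doses)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct doses, got {len(np.unique(doses))}"
        )
    if dose_domain is None:
        dose_domain = (float(doses[0]), float(doses[-1]))

    mid = len(doses) // 2
    a0, b0, c0 = _exact_three_point(
        doses[[0, mid, -1]], resps[[0, mid, -1]]
    )

    if len(doses) > 3:
        def residuals(theta: np.ndarray) -> np.ndarray:
            a, b, c = theta
            return a + b / (doses - c) - resps

        sol = least_squares(
            residuals,
            x0=np.array([a0, b0, c0]),
            method="lm",
            ftol=1e-14,
            xtol=1e-14,
            gtol=1e-14,
        )
        a0, b0, c0 = (float(v) for v in sol.x)

    if form is CurveForm.SATURATING:
        # standard (a, b, c)  ->  saturating (A, B, C) with C=-c, B=b/c, A=a-B
        C = -c0
        B = b0 / c0
        A = a0 - B
        a0, b0, c0 = A, B, C

    return CalibrationCurve(
        channel=Channel(channel),
        a=a0,
        b=b0,
        c=c0,
        dose_domain=dose_domain,
        lot_id=lot_id,
        form=form,
    )
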
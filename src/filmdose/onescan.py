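"""One-scan protocol: session rescaling of a generic calibration curve.

A published ("generic") calibration curve N(D) for a film lot was measured
on one scanner under one set of conditions.  A different scanner, scan
temperature or time-after-exposure shifts the absolute response, to good
approximation affinely per color channel.  Scanning the application film
together with two reference strips of the same lot -- one unexposed, one at
a known dose (default 160 cGy) -- pins down that affine map:

    X(D) = alpha + beta * N(D)

with (alpha, beta) the unique solution of the 2x2 linear system through the
two reference readings (X_i at dose D_i, N_i = N(D_i)):

    beta  = (X1 - X2) / (N1 - N2)
    alpha = (N1*X2 - N2*X1) / (N1 - N2)

The rational curve family is closed under affine response maps, so the
session curve is again a valid CalibrationCurve.

The protocol also relaxes the post-exposure wait: if all films are exposed
within a time window t, a delay of at least 4t between exposure and scanning
keeps the dose error from post-exposure darkening below 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .calibration import CalibrationCurve, CalibrationPoint, eval_response
from .errors import (
    DegenerateReferencesError,
    RescaleRejectedError,
    TimingValidationError,
)

__all__ = [
    "ReferencePair",
    "RescaleParams",
    "TimingCheck",
    "DEFAULT_REFERENCE_DOSE",
    "compute_rescale",
    "apply_rescale",
    "check_timing",
]

#: Default dose of the exposed reference strip, cGy.  Chosen similar to the
#: highest dose on the application film.
DEFAULT_REFERENCE_DOSE = 160.0


@dataclass(frozen=True)
class ReferencePair:
    """Measured responses of the unexposed and the known-dose reference strip."""

    point_low: CalibrationPoint
    point_high: CalibrationPoint

    def __post_init__(self) -> None:
        if self.point_low.dose != 0:
            raise ValueError("point_low must be the unexposed strip (dose 0)")
        if not self.point_high.dose > 0:
            raise ValueError("point_high dose must be > 0")
        if self.point_low.response == self.point_high.response:
            raise DegenerateReferencesError(
                "reference responses are identical; cannot rescale"
            )


@dataclass(frozen=True)
class RescaleParams:
    """Per-channel affine map X = alpha + beta * N adapting the generic curve."""

    channel: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.beta == 0:
            raise ValueError("beta must be nonzero")


@dataclass(frozen=True)
class TimingCheck:
    """Outcome of the 4t exposure-to-scan timing rule."""

    ok: bool
    required_minimum_minutes: float
    exposure_to_scan_minutes: float


def compute_rescale(
    generic: CalibrationCurve, refs: ReferencePair
) -> RescaleParams:
    """Solve the two-reference-film system for the session (alpha, beta).

    N1, N2 are the generic-curve responses at the reference doses; X1, X2
    the measured session responses of the two strips.
    """
    n1 = eval_response(generic, refs.point_low.dose)
    n2 = eval_response(generic, refs.point_high.dose)
    if n1 == n2:
        raise DegenerateReferencesError(
            "generic curve gives equal responses at the two reference doses"
        )
    x1 = refs.point_low.response
    x2 = refs.point_high.response
    beta = (x1 - x2) / (n1 - n2)
    alpha = (n1 * x2 - n2 * x1) / (n1 - n2)
    return RescaleParams(channel=generic.channel.value, alpha=alpha, beta=beta)


def apply_rescale(
    generic: CalibrationCurve, params: RescaleParams
) -> CalibrationCurve:
    """Session-specific curve alpha + beta * N(D).

    The rational forms are closed under affine maps of the response: for the
    standard form a' = alpha + beta*a, b' = beta*b with the pole c unchanged
    (likewise A', B' for the saturating form).  A rescale that would produce
    a non-monotone curve is rejected.
    """
    a2 = params.alpha + params.beta * generic.a
    b2 = params.beta * generic.b
    try:
        return replace(generic, a=a2, b=b2)
    except Exception as exc:  # curve invariant violated
        raise RescaleRejectedError(
            f"rescale by (alpha={params.alpha:g}, beta={params.beta:g}) "
            f"produces an invalid curve: {exc}"
        ) from exc


def check_timing(
    exposure_window_minutes: float, exposure_to_scan_minutes: float
) -> TimingCheck:
    """Enforce the 4t rule: scan no earlier than 4x the exposure window.

    Films exposed within a window t and scanned after a delay >= 4t differ
    in post-exposure darkening by less than 0.5% in dose.
    """
    if not exposure_window_minutes > 0:
        raise TimingValidationError(
            f"exposure window must be > 0 minutes, got {exposure_window_minutes}"
        )
    if exposure_to_scan_minutes < 0:
        raise TimingValidationError(
            f"exposure-to-scan delay must be >= 0, got {exposure_to_scan_minutes}"
        )
    required = 4.0 * exposure_window_minutes
    return TimingCheck(
        ok=exposure_to_scan_minutes >= required,
        required_minimum_minutes=required,
        exposure_to_scan_minutes=exposure_to_scan_minutes,
    )
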
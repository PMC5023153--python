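"""End-to-end film-QA workflows built from the library primitives.

These functions wire the full protocol together -- strip calibration,
One-scan session rescaling, triple-channel reconstruction, gamma analysis
-- both for simulated studies (``simulated_vmat_qa``) and for pieces the
CLI exposes over real scan files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve, CalibrationPoint, Channel, fit_calibration
from .film_io import extract_roi_response
from .gamma import GammaParams, GammaResult, gamma_map
from .multichannel import (
    DisturbanceMap,
    DoseMap,
    FilmScan,
    SolverSettings,
    smooth_scan,
    triple_channel_dose,
)
from .onescan import (
    DEFAULT_REFERENCE_DOSE,
    ReferencePair,
    apply_rescale,
    compute_rescale,
)
from .simulate import (
    DEFAULT_SEED,
    PhantomPlan,
    ScannerModel,
    default_lot_curves,
    facility_b_scanner,
    make_vmat_pattern,
    reference_scanner,
    render_scan,
    render_strip_set,
)

__all__ = [
    "CALIBRATION_DOSES",
    "fit_generic_from_strips",
    "rescale_curves_from_strips",
    "QAOutcome",
    "simulated_vmat_qa",
]

#: Calibration exposure series: unexposed plus 80/160/320 cGy strips.
CALIBRATION_DOSES = (0.0, 80.0, 160.0, 320.0)


def _strip_roi(scan: FilmScan) -> tuple[int, int, int, int]:
    """Central rectangle of a strip scan, margins of 1/8 on every side."""
    h, w = scan.shape
    return (h // 8, h - h // 8, w // 8, w - w // 8)


def fit_generic_from_strips(
    strips: list[FilmScan],
    doses: list[float],
    *,
    lot_id: str = "",
    dose_domain: tuple[float, float] | None = None,
) -> tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve]:
    """Fit the three per-channel curves from uniformly exposed strips."""
    curves = []
    for ch in (Channel.R, Channel.G, Channel.B):
        points = [
            CalibrationPoint(dose=d, response=extract_roi_response(s, _strip_roi(s), ch))
            for s, d in zip(strips, doses)
        ]
        curves.append(
            fit_calibration(points, channel=ch, lot_id=lot_id, dose_domain=dose_domain)
        )
    return tuple(curves)


def rescale_curves_from_strips(
    generic: tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve],
    ref_unexposed: FilmScan,
    ref_exposed: FilmScan,
    reference_dose: float = DEFAULT_REFERENCE_DOSE,
) -> tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve]:
    """One-scan rescaling of all three channels from the two reference strips."""
    session = []
    for curve, ch in zip(generic, (Channel.R, Channel.G, Channel.B)):
        refs = ReferencePair(
            point_low=CalibrationPoint(
                0.0, extract_roi_response(ref_unexposed, _strip_roi(ref_unexposed), ch)
            ),
            point_high=CalibrationPoint(
                reference_dose,
                extract_roi_response(ref_exposed, _strip_roi(ref_exposed), ch),
            ),
        )
        session.append(apply_rescale(curve, compute_rescale(curve, refs)))
    return tuple(session)


@dataclass
class QAOutcome:
    """Everything the simulated QA run produced, for inspection and tests."""

    plan: PhantomPlan
    scan: FilmScan
    dose_map: DoseMap
    disturbance: DisturbanceMap
    gamma: GammaResult
    session_curves: tuple[CalibrationCurve, ...]

    @property
    def pass_fraction(self) -> float:
        return self.gamma.pass_fraction


def simulated_vmat_qa(
    seed: int = DEFAULT_SEED,
    shape: tuple[int, int] = (200, 200),
    *,
    cross_scanner: bool = True,
    use_onescan: bool = True,
    noise_sd: float = 0.002,
    disturbance_amplitude: float = 0.02,
    levels: tuple[float, float, float] = (80.0, 160.0, 240.0),
    gamma_params: GammaParams | None = None,
    solver: SolverSettings = SolverSettings(),
    smooth_sigma_px: float = 1.0,
) -> QAOutcome:
    """Simulation twin of the two-facility VMAT QA study.

    Calibration strips are scanned at facility A (identity scanner).  The
    application film and the two reference strips (0 and 160 cGy) are
    scanned either at facility B -- a scanner with a different per-channel
    affine response -- (``cross_scanner=True``) or back at facility A.  With
    ``use_onescan=False`` facility A's calibration is applied to facility
    B's scan directly, the failure mode the protocol exists to fix.

    Returns the full chain of intermediate products; ``pass_fraction`` is
    the 3%/3 mm gamma passing rate against the ground-truth plan.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=4)

    plan = make_vmat_pattern(shape, levels=levels, seed=int(seeds[0]))
    lot = default_lot_curves()

    scan_a = reference_scanner(noise_sd=noise_sd, seed=int(seeds[1]))
    cal_strips = render_strip_set(list(CALIBRATION_DOSES), lot, scan_a)
    generic = fit_generic_from_strips(
        cal_strips, list(CALIBRATION_DOSES), lot_id=lot[0].lot_id
    )

    if cross_scanner:
        session_scanner = facility_b_scanner(noise_sd=noise_sd, seed=int(seeds[2]))
    else:
        session_scanner = reference_scanner(noise_sd=noise_sd, seed=int(seeds[2]))

    ref_strips = render_strip_set(
        [0.0, DEFAULT_REFERENCE_DOSE], lot, session_scanner
    )
    app_scanner = ScannerModel(
        session_scanner.scanner_id,
        gain=session_scanner.gain,
        offset=session_scanner.offset,
        noise_sd=session_scanner.noise_sd,
        seed=int(seeds[3]),
    )
    scan = render_scan(
        plan, lot, app_scanner, disturbance_amplitude=disturbance_amplitude
    )

    if use_onescan:
        session_curves = rescale_curves_from_strips(
            generic, ref_strips[0], ref_strips[1]
        )
    else:
        session_curves = generic

    dose_map, disturbance = triple_channel_dose(
        smooth_scan(scan, smooth_sigma_px), session_curves, solver
    )

    if gamma_params is None:
        gamma_params = GammaParams(max_gamma=1.5)
    reference = DoseMap(dose=plan.dose, spacing_mm=plan.spacing_mm)
    result = gamma_map(dose_map, reference, gamma_params)

    return QAOutcome(
        plan=plan,
        scan=scan,
        dose_map=dose_map,
        disturbance=disturbance,
        gamma=result,
        session_curves=session_curves,
    )
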
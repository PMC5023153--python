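"""Synthetic film scans with the statistical structure the method assumes.

The simulator inverts the measurement chain: a ground-truth dose plane is
pushed through the per-channel rational dose-response curves of a film lot,
a scanner-specific per-channel affine response transform (emulating two
facilities whose flatbed scanners report different absolute responses for
the same film), a smooth multiplicative film-thickness-like disturbance
field, and additive pixel noise, before 16-bit quantization:

    pixel_k = round(65535 * [ gain_k * X_k(D) * (1 + Delta(r))
                              + offset_k + eps ]),   eps ~ N(0, noise_sd)

Everything is deterministic given the scanner seed, so full-chain claims
(One-scan exactness, triple-channel disturbance recovery, gamma pass rates)
are testable without physical film.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationCurve, Channel
from .errors import DomainError
from .multichannel import MM_PER_INCH, FilmScan

__all__ = [
    "ScannerModel",
    "PhantomPlan",
    "DEFAULT_SEED",
    "default_lot_curves",
    "reference_scanner",
    "facility_b_scanner",
    "make_vmat_pattern",
    "disturbance_field",
    "render_scan",
    "render_strip_set",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20140129
DEFAULT_DPI = 72.0
DEFAULT_SPACING_MM = MM_PER_INCH / DEFAULT_DPI  # 0.3528 mm at 72 dpi


@dataclass(frozen=True)
class ScannerModel:
    """Per-channel affine response transform plus pixel noise of one scanner."""

    scanner_id: str
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if min(self.gain) <= 0:
            raise ValueError("scanner gains must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomPlan:
    """Ground-truth planned dose plane (cGy) for the simulated treatment."""

    dose: np.ndarray
    spacing_mm: float
    description: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)


def default_lot_curves(
    lot_id: str = "SIMLOT-A", dose_domain: tuple[float, float] = (0.0, 400.0)
) -> tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve]:
    """EBT3-like per-channel curves of the simulated film lot.

    Red is the most dose-sensitive channel at low dose, blue the least,
    mirroring the relative channel sensitivities of real radiochromic film;
    all responses start near 1 (clear film) and fall monotonically.
    """
    return (
        CalibrationCurve(Channel.R, a=0.18, b=40.0, c=-50.0,
                         dose_domain=dose_domain, lot_id=lot_id),
        CalibrationCurve(Channel.G, a=0.30, b=45.0, c=-65.0,
                         dose_domain=dose_domain, lot_id=lot_id),
        CalibrationCurve(Channel.B, a=0.50, b=25.0, c=-55.0,
                         dose_domain=dose_domain, lot_id=lot_id),
    )


def reference_scanner(noise_sd: float = 0.0, seed: int = DEFAULT_SEED) -> ScannerModel:
    """The calibration facility's scanner: identity response transform."""
    return ScannerModel("facility-A", noise_sd=noise_sd, seed=seed)


def facility_b_scanner(noise_sd: float = 0.0, seed: int = DEFAULT_SEED) -> ScannerModel:
    """A second facility's scanner whose absolute response differs.

    The default per-channel gains (0.97, 0.97, 0.98) and offsets
    (+0.02, +0.02, +0.015) produce multi-percent dose errors near 160 cGy
    when the other facility's calibration is applied without rescaling.
    """
    return ScannerModel(
        "facility-B",
        gain=(0.97, 0.97, 0.98),
        offset=(0.02, 0.02, 0.015),
        noise_sd=noise_sd,
        seed=seed,
    )


def make_vmat_pattern(
    shape: tuple[int, int] = (200, 200),
    levels: tuple[float, float, float] = (80.0, 160.0, 240.0),
    spacing_mm: float = DEFAULT_SPACING_MM,
    seed: int = DEFAULT_SEED,
    *,
    bath_dose: float = 10.0,
    edge_sigma_mm: float = 2.0,
    dose_domain: tuple[float, float] = (0.0, 400.0),
) -> PhantomPlan:
    """Three-level dose-painting pattern emulating a highly modulated plan.

    Three nested smooth-edged superelliptical regions at the ascending
    ``levels`` sit on a low-dose bath, the boost (highest) level forming a
    broad central core surrounded by thinner intermediate shells -- the
    prescription structure of a dose-painting boost target.  Edges are
    smoothed with a Gaussian of ``edge_sigma_mm`` to create penumbra-like
    gradients.  Region centers are jittered by a few pixels from ``seed``
    so different seeds give different (but always deterministic)
    geometries.

    The region sizes deliberately put most of the target area on dose
    plateaus that are wide compared with the 3 mm distance-to-agreement
    scale of the gamma test; on a plan dominated by penumbra, a systematic
    dose error can always be masked by a nearby penumbra dose, which would
    make the gamma comparison insensitive by construction.
    """
    if not (levels[0] < levels[1] < levels[2]):
        raise ValueError("levels must be ascending")
    lo, hi = dose_domain
    if levels[2] > hi or bath_dose < lo:
        raise DomainError(
            f"dose levels {levels} / bath {bath_dose} outside domain {dose_domain}"
        )
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    dose = np.full((h, w), float(bath_dose))
    semi = [(0.47, 0.48), (0.43, 0.44), (0.38, 0.39)]
    for level, (sy, sx) in zip(levels, semi):
        cy = h / 2 + rng.uniform(-3, 3)
        cx = w / 2 + rng.uniform(-3, 3)
        inside = (
            np.abs((yy - cy) / (sy * h)) ** 4 + np.abs((xx - cx) / (sx * w)) ** 4
        ) <= 1.0
        dose[inside] = level

    sigma_px = edge_sigma_mm / spacing_mm
    dose = gaussian_filter(dose, sigma=sigma_px, mode="nearest")
    return PhantomPlan(
        dose=dose,
        spacing_mm=spacing_mm,
        description=f"3-level dose painting {levels} cGy on {bath_dose} cGy bath",
    )


def _render(
    dose: np.ndarray,
    curves: tuple[CalibrationCurve, ...],
    scanner: ScannerModel,
    rng: np.random.Generator,
    disturbance: np.ndarray | None,
    dpi: float,
) -> FilmScan:
    for c in curves:
        lo, hi = c.dose_domain
        if dose.min() < lo or dose.max() > hi:
            raise DomainError(
                f"plan doses [{dose.min():g}, {dose.max():g}] exceed curve "
                f"domain [{lo:g}, {hi:g}]"
            )
    h, w = dose.shape
    out = np.empty((3, h, w), dtype=np.uint16)
    clipped = 0
    for k, curve in enumerate(curves):
        resp = curve._eval_unchecked(dose)
        if disturbance is not None:
            resp = resp * (1.0 + disturbance)
        resp = scanner.gain[k] * resp + scanner.offset[k]
        if scanner.noise_sd > 0:
            resp = resp + rng.normal(0.0, scanner.noise_sd, size=resp.shape)
        bad = (resp <= 0) | (resp > 1)
        clipped += int(bad.sum())
        resp = np.clip(resp, 0.0, 1.0)
        out[k] = np.round(resp * 65535.0).astype(np.uint16)
    if clipped > 0.01 * 3 * h * w:
        log.warning(
            "%.1f%% of rendered responses left (0, 1] and were clipped",
            100 * clipped / (3 * h * w),
        )
    return FilmScan(pixels=out, dpi=dpi, scanner_id=scanner.scanner_id)


def disturbance_field(
    shape: tuple[int, int],
    spacing_mm: float,
    amplitude: float,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smooth multiplicative disturbance: Gaussian-filtered white noise.

    The field is scaled to peak absolute value ``amplitude``; ``corr_mm``
    sets the Gaussian correlation length.  Consumes exactly one
    ``standard_normal(shape)`` draw from ``rng``.
    """
    raw = rng.standard_normal(shape)
    smooth = gaussian_filter(raw, sigma=corr_mm / spacing_mm, mode="nearest")
    peak = np.abs(smooth).max()
    if peak == 0:
        raise ValueError("degenerate disturbance field")
    return amplitude * smooth / peak


def render_scan(
    plan: PhantomPlan,
    curves: tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve],
    scanner: ScannerModel,
    disturbance_amplitude: float = 0.0,
    disturbance_corr_mm: float = 10.0,
) -> FilmScan:
    """Render the application-film scan of a planned dose distribution.

    The disturbance is a Gaussian-smoothed random field (correlation length
    ``disturbance_corr_mm``) scaled to peak amplitude
    ``disturbance_amplitude``, multiplying the film response before the
    scanner transform -- emulating film-thickness variation.  Deterministic
    given the scanner seed.
    """
    rng = np.random.default_rng(scanner.seed)
    disturbance = None
    if disturbance_amplitude != 0.0:
        disturbance = disturbance_field(
            plan.dose.shape, plan.spacing_mm, disturbance_amplitude,
            disturbance_corr_mm, rng,
        )
    dpi = MM_PER_INCH / plan.spacing_mm
    return _render(plan.dose, curves, scanner, rng, disturbance, dpi)


def render_strip_set(
    doses: list[float],
    curves: tuple[CalibrationCurve, CalibrationCurve, CalibrationCurve],
    scanner: ScannerModel,
    strip_shape: tuple[int, int] = (40, 160),
    dpi: float = DEFAULT_DPI,
) -> list[FilmScan]:
    """Uniformly exposed film strips (calibration or reference) on one scanner.

    All strips share one noise stream seeded from the scanner, emulating a
    single scan frame containing every strip.
    """
    rng = np.random.default_rng(scanner.seed)
    strips = []
    for d in doses:
        plane = np.full(strip_shape, float(d))
        strips.append(_render(plane, curves, scanner, rng, None, dpi))
    return strips
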
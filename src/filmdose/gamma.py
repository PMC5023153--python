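"""Gamma-index comparison of a measured dose map against a planned grid.

For each evaluated measured pixel m at position r_m with dose d_m, the gamma
index against a reference (plan) distribution d_r is

    gamma(m) = min over r  sqrt( (d_m - d_r(r))^2 / dDtol^2
                                 + |r - r_m|^2 / dta^2 )

with dDtol = dose_tol_percent of the normalization dose (default: the global
maximum of the reference map) and dta the distance-to-agreement criterion in
mm.  A pixel passes when gamma <= 1; the passing fraction is taken over
pixels whose reference dose exceeds a low-dose threshold.

The search minimizes over the reference distribution, interpolated
bilinearly, on rings of increasing radius around each measured pixel
(radial step = pixel spacing / interp_subdivisions, capped at
search_radius_factor * dta).  Because every candidate at distance s
contributes at least (s/dta)^2, a pixel's minimum is final once the ring
distance alone exceeds its current best value -- the search self-terminates
and the result equals an exhaustive search at the same sampling resolution.

If ``max_gamma`` is set (e.g. 1.5), pixels whose gamma is already known to
exceed it stop searching early; their reported gamma is then a lower bound,
but pass/fail against gamma <= 1 (and hence the passing fraction) is exact
for any max_gamma >= 1.  Leave it at None for fully resolved gamma values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import EmptyEvaluationError, GeometryError, NormalizationError
from .multichannel import DoseMap

__all__ = ["GammaParams", "GammaResult", "gamma_map", "pass_rate"]


@dataclass(frozen=True)
class GammaParams:
    """Criteria and numerical settings of the gamma evaluation."""

    dose_tol_percent: float = 3.0
    dta_mm: float = 3.0
    normalization: Literal["global_max_of_reference", "fixed_value"] = (
        "global_max_of_reference"
    )
    fixed_norm_cgy: float | None = None
    low_dose_threshold_percent: float = 10.0
    search_radius_factor: float = 3.0
    interp_subdivisions: int = 10
    max_gamma: float | None = None

    def __post_init__(self) -> None:
        if min(self.dose_tol_percent, self.dta_mm, self.search_radius_factor) <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.interp_subdivisions < 1:
            raise ValueError("interp_subdivisions must be >= 1")
        if not 0 <= self.low_dose_threshold_percent < 100:
            raise ValueError("low_dose_threshold_percent must be in [0, 100)")
        if self.normalization == "fixed_value" and not self.fixed_norm_cgy:
            raise ValueError("fixed_value normalization requires fixed_norm_cgy")
        if self.max_gamma is not None and self.max_gamma < 1.0:
            raise ValueError("max_gamma, when set, must be >= 1")


@dataclass
class GammaResult:
    """Per-pixel gamma values and the passing fraction over evaluated pixels."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray
    pass_fraction: float
    params: GammaParams

    def histogram(self, bins: int = 20, upper: float = 2.0):
        """(counts, edges) of evaluated gamma values clipped at ``upper``."""
        vals = np.minimum(self.gamma[self.evaluated_mask], upper)
        return np.histogram(vals, bins=bins, range=(0.0, upper))


def _resample_reference(reference: DoseMap, measured: DoseMap) -> np.ndarray:
    """Reference dose bilinearly resampled onto the measured grid.

    Both maps share the convention that (0, 0) mm is the top-left pixel
    center.  Measured pixels outside the reference extent are NaN.
    """
    if reference.spacing_mm == measured.spacing_mm and (
        reference.shape == measured.shape
    ):
        return reference.dose.copy()
    h, w = measured.shape
    rows = np.arange(h) * measured.spacing_mm / reference.spacing_mm
    cols = np.arange(w) * measured.spacing_mm / reference.spacing_mm
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = map_coordinates(
        reference.dose, [rr, cc], order=1, mode="constant", cval=np.nan
    )
    return out


def gamma_map(
    measured: DoseMap, reference: DoseMap, params: GammaParams = GammaParams()
) -> GammaResult:
    """Gamma evaluation of ``measured`` against the ``reference`` plan grid."""
    ref_on_meas = _resample_reference(reference, measured)
    if not np.isfinite(ref_on_meas).any():
        raise GeometryError("measured and reference maps do not overlap")

    if params.normalization == "fixed_value":
        norm = float(params.fixed_norm_cgy)  # validated non-null
    else:
        norm = float(np.nanmax(reference.dose))
    if not norm > 0:
        raise NormalizationError(f"normalization dose must be > 0, got {norm}")
    dd_tol = params.dose_tol_percent / 100.0 * norm
    dta = params.dta_mm

    evaluated = np.isfinite(ref_on_meas) & (
        ref_on_meas >= params.low_dose_threshold_percent / 100.0 * norm
    )
    if not evaluated.any():
        raise EmptyEvaluationError("no pixels above the low-dose threshold")

    h, w = measured.shape
    spacing = measured.spacing_mm
    step_mm = spacing / params.interp_subdivisions
    radius_mm = params.search_radius_factor * dta

    # distance-zero term on the evaluated pixels
    rows, cols = np.nonzero(evaluated)
    meas_vals = measured.dose[rows, cols]
    g2 = ((meas_vals - ref_on_meas[rows, cols]) / dd_tol) ** 2

    # rings of increasing radius; pixels drop out once the distance term
    # alone exceeds their current minimum (or the max_gamma cap)
    ref_spacing_px = reference.spacing_mm
    active = np.arange(rows.size)
    n_steps = int(np.floor(radius_mm / step_mm))
    cap2 = np.inf if params.max_gamma is None else params.max_gamma**2
    for i in range(1, n_steps + 1):
        s = i * step_mm
        dist2 = (s / dta) ** 2
        keep = g2[active] > max(dist2, 0.0)
        if cap2 < np.inf:
            keep &= np.minimum(g2[active], cap2) > dist2
        active = active[keep]
        if active.size == 0:
            break
        n_ang = max(8, int(np.ceil(2 * np.pi * s / step_mm)))
        ang = np.arange(n_ang) * (2 * np.pi / n_ang)
        dr = s * np.sin(ang) / ref_spacing_px
        dc = s * np.cos(ang) / ref_spacing_px
        # positions of ring points in reference pixel coordinates
        base_r = rows[active] * spacing / ref_spacing_px
        base_c = cols[active] * spacing / ref_spacing_px
        # chunk over angles to bound memory
        best_dose_term = np.full(active.size, np.inf)
        a_chunk = max(1, int(2_000_000 // max(active.size, 1)))
        for a0 in range(0, n_ang, a_chunk):
            rr = base_r[:, None] + dr[None, a0 : a0 + a_chunk]
            cc = base_c[:, None] + dc[None, a0 : a0 + a_chunk]
            vals = map_coordinates(
                reference.dose, [rr, cc], order=1, mode="constant", cval=np.nan
            )
            diff2 = ((meas_vals[active][:, None] - vals) / dd_tol) ** 2
            diff2 = np.nan_to_num(diff2, nan=np.inf)  # outside reference extent
            best_dose_term = np.minimum(best_dose_term, diff2.min(axis=1))
        cand = best_dose_term + dist2
        g2[active] = np.minimum(g2[active], cand)

    gamma = np.full((h, w), np.nan)
    gamma[rows, cols] = np.sqrt(g2)
    passing = 100.0 * np.count_nonzero(g2 <= 1.0) / g2.size
    return GammaResult(
        gamma=gamma,
        evaluated_mask=evaluated,
        pass_fraction=round(passing, 1),
        params=params,
    )


def pass_rate(result: GammaResult) -> float:
    """Passing percentage: 100 x (evaluated pixels with gamma <= 1) / evaluated."""
    g = result.gamma[result.evaluated_mask]
    if g.size == 0:
        raise EmptyEvaluationError("no evaluated pixels")
    return round(100.0 * np.count_nonzero(g <= 1.0) / g.size, 1)
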
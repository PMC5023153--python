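"""Triple-channel (D, Delta) solver and dose-map reconstruction."""

import numpy as np
import pytest

from filmdose.errors import InvalidPixelError
from filmdose.multichannel import (
    DoseMap,
    FilmScan,
    single_channel_dose,
    smooth_scan,
    solve_pixel,
    triple_channel_dose,
)
from filmdose.simulate import (
    PhantomPlan,
    disturbance_field,
    reference_scanner,
    render_scan,
)

from .conftest import render_triplet


def brute_force_solve(x, curves, d_step=0.1, delta_step=1e-3, delta_max=0.1):
    """Exhaustive 2-D grid minimization of F(D, Delta) -- independent oracle."""
    d_min, d_max = curves[0].dose_domain
    doses = np.arange(d_min, d_max + d_step / 2, d_step)
    deltas = np.arange(-delta_max, delta_max + delta_step / 2, delta_step)
    X = np.stack([c._eval_unchecked(doses) for c in curves])  # (3, G)
    pred = (1.0 + deltas[:, None, None]) * X[None]  # (M, 3, G)
    f = ((np.asarray(x)[None, :, None] - pred) ** 2).sum(axis=1)  # (M, G)
    i, j = np.unravel_index(np.argmin(f), f.shape)
    return float(doses[j]), float(deltas[i])


def objective(x, curves, dose, delta):
    """F(D, Delta) evaluated directly from its definition."""
    pred = np.array(
        [(1.0 + delta) * c._eval_unchecked(np.asarray(dose)) for c in curves]
    )
    return float(((np.asarray(x) - pred) ** 2).sum())


def dose_resolution(curves, dose, d_step=0.1, delta_step=1e-3):
    """Effective dose resolution of the brute-force grid at ``dose``.

    Quantizing Delta to the grid shifts the conditional dose minimum by
    roughly (sum_k X_k X'_k / sum_k X'_k^2) per unit Delta, so the oracle
    can sit a corresponding distance from the continuum minimum.
    """
    d = np.asarray(float(dose))
    X = np.array([c._eval_unchecked(d) for c in curves])
    dX = np.array([-c.b / (float(dose) - c.c) ** 2 for c in curves])
    coupling = abs(float((X * dX).sum() / (dX * dX).sum()))
    return d_step + delta_step * coupling


class TestSolvePixel:
    def test_exact_triplet_recovers_dose_and_zero_delta(self, lot_curves):
        x = render_triplet(lot_curves, 120.0)
        d, delta = solve_pixel(x, lot_curves)
        assert d == pytest.approx(120.0, abs=0.01)
        assert delta == pytest.approx(0.0, abs=1e-4)

    def test_scaled_triplet_recovers_disturbance(self, lot_curves):
        x = render_triplet(lot_curves, 120.0, delta=0.02)
        d, delta = solve_pixel(x, lot_curves)
        assert d == pytest.approx(120.0, abs=0.01)
        assert delta == pytest.approx(0.02, abs=1e-4)

    def test_consistent_channels_give_zero_delta(self, lot_curves):
        """Exact per-channel consistency implies Delta = 0 to 1e-6."""
        for dose in (15.0, 80.0, 160.0, 240.0, 350.0):
            _, delta = solve_pixel(render_triplet(lot_curves, dose), lot_curves)
            assert delta == pytest.approx(0.0, abs=1e-6)

    def test_scale_equivariance(self, lot_curves):
        """Multiplying the triplet by (1+s) shifts Delta by s, dose fixed."""
        x = render_triplet(lot_curves, 140.0)
        d0, delta0 = solve_pixel(x, lot_curves)
        for s in (-0.03, 0.015, 0.05):
            d, delta = solve_pixel(x * (1.0 + s), lot_curves)
            assert d == pytest.approx(d0, abs=0.01)
            assert delta - delta0 == pytest.approx(s, abs=1e-4)

    def test_matches_brute_force_grid_search(self, lot_curves):
        """Solver minima equal an exhaustive (D, Delta) grid search on 100
        random noiseless pixels, within the oracle's effective resolution."""
        rng = np.random.default_rng(7)
        doses = rng.uniform(5.0, 350.0, 100)
        deltas = rng.uniform(-0.05, 0.05, 100)
        for dose, delta in zip(doses, deltas):
            x = render_triplet(lot_curves, dose, delta)
            d_s, del_s = solve_pixel(x, lot_curves)
            d_b, del_b = brute_force_solve(x, lot_curves)
            assert d_s == pytest.approx(d_b, abs=dose_resolution(lot_curves, d_s))
            assert del_s == pytest.approx(del_b, abs=1e-3)
            # the refined solver minimum is never worse than the grid's
            assert objective(x, lot_curves, d_s, del_s) <= (
                objective(x, lot_curves, d_b, del_b) + 1e-12
            )

    def test_all_zero_triplet_rejected(self, lot_curves):
        with pytest.raises(InvalidPixelError):
            solve_pixel((0.0, 0.0, 0.0), lot_curves)


def _uniform_scan(curves, dose, shape=(20, 30), dpi=72.0):
    resp = np.stack(
        [np.full(shape, c._eval_unchecked(np.asarray(float(dose)))) for c in curves]
    )
    return FilmScan(
        pixels=np.round(resp * 65535).astype(np.uint16), dpi=dpi, scanner_id="t"
    )


class TestSingleChannel:
    def test_uniform_scan_inverts_to_uniform_dose(self, lot_curves):
        scan = _uniform_scan(lot_curves, 150.0)
        dm = single_channel_dose(scan, lot_curves[0], "R")
        # 16-bit quantization limits accuracy to ~0.02 cGy at this dose
        assert np.allclose(dm.dose, 150.0, atol=0.05)
        assert not dm.flagged.any()

    def test_unexposed_scan_gives_zero_dose(self, lot_curves):
        scan = _uniform_scan(lot_curves, 0.0)
        dm = single_channel_dose(scan, lot_curves[0], "R")
        assert np.allclose(dm.dose, 0.0, atol=0.01)  # 16-bit quantization

    def test_out_of_range_pixels_clamped_and_flagged(self, lot_curves):
        scan = _uniform_scan(lot_curves, 150.0)
        px = scan.pixels.copy()
        px[0, 0, 0] = 65535  # brighter than the unexposed response
        dm = single_channel_dose(FilmScan(px, 72.0), lot_curves[0], "R")
        assert dm.flagged[0, 0]
        assert dm.dose[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_channel_mismatch_rejected(self, lot_curves):
        with pytest.raises(ValueError):
            single_channel_dose(_uniform_scan(lot_curves, 50.0), lot_curves[0], "G")


class TestTripleChannelMap:
    def test_noiseless_scan_recovers_plan(self, lot_curves):
        plan = PhantomPlan(
            np.linspace(10, 350, 300).reshape(10, 30), spacing_mm=0.3528
        )
        scan = render_scan(plan, lot_curves, reference_scanner(seed=3))
        dm, dist = triple_channel_dose(scan, lot_curves)
        assert np.max(np.abs(dm.dose - plan.dose)) < 0.05
        assert np.max(np.abs(dist.delta)) < 1e-3

    def test_disturbance_field_recovered(self, lot_curves):
        """Noiseless scan with a smooth 3% disturbance: the recovered map
        matches the simulated field to better than 1e-3 RMS."""
        from filmdose.simulate import make_vmat_pattern

        plan = make_vmat_pattern((64, 64), seed=5)
        scanner = reference_scanner(seed=9)
        scan = render_scan(plan, lot_curves, scanner, disturbance_amplitude=0.03)
        truth = disturbance_field(
            (64, 64), plan.spacing_mm, 0.03, 10.0, np.random.default_rng(9)
        )
        _, dist = triple_channel_dose(scan, lot_curves)
        rms = np.sqrt(np.nanmean((dist.delta - truth) ** 2))
        assert rms < 1e-3

    def test_noisy_triple_channel_beats_best_single_channel(self, lot_curves):
        """With pixel noise and a thickness-like disturbance present, the
        triple-channel reconstruction has lower dose RMS error than the best
        single channel on the very same scan: a single channel cannot tell a
        5% thickness variation from a dose change."""
        plan = PhantomPlan(np.full((60, 60), 160.0), spacing_mm=0.3528)
        scanner = reference_scanner(noise_sd=0.002, seed=11)
        scan = render_scan(plan, lot_curves, scanner,
                           disturbance_amplitude=0.05, disturbance_corr_mm=5.0)
        dm3, _ = triple_channel_dose(scan, lot_curves)
        rms3 = np.sqrt(np.mean((dm3.dose - plan.dose) ** 2))
        rms1 = min(
            np.sqrt(
                np.mean(
                    (single_channel_dose(scan, c, ch).dose - plan.dose) ** 2
                )
            )
            for c, ch in zip(lot_curves, "RGB")
        )
        assert rms3 < rms1

    def test_reconstruction_is_deterministic(self, lot_curves):
        plan = PhantomPlan(np.full((16, 16), 120.0), spacing_mm=0.3528)
        scan = render_scan(plan, lot_curves, reference_scanner(noise_sd=0.002, seed=2))
        a, _ = triple_channel_dose(scan, lot_curves)
        b, _ = triple_channel_dose(scan, lot_curves)
        assert np.array_equal(a.dose, b.dose)

    def test_all_zero_pixels_masked(self, lot_curves):
        scan = _uniform_scan(lot_curves, 100.0)
        px = scan.pixels.copy()
        px[:, 2, 3] = 0
        dm, dist = triple_channel_dose(FilmScan(px, 72.0), lot_curves)
        assert dm.flagged[2, 3]
        assert np.isnan(dm.dose[2, 3])
        assert np.isnan(dist.delta[2, 3])


def test_smooth_scan_reduces_noise_preserves_mean(lot_curves):
    rng = np.random.default_rng(5)
    base = np.full((3, 50, 50), 30000.0)
    noisy = base + rng.normal(0, 200, base.shape)
    scan = FilmScan(np.clip(noisy, 0, 65535).astype(np.uint16), 72.0)
    sm = smooth_scan(scan, 1.0)
    assert sm.pixels.std() < 0.5 * scan.pixels.std()
    assert abs(float(sm.pixels.mean()) - float(scan.pixels.mean())) < 20


def test_film_scan_validation():
    with pytest.raises(ValueError):
        FilmScan(np.zeros((2, 4, 4), dtype=np.uint16), 72.0)
    with pytest.raises(ValueError):
        FilmScan(np.zeros((3, 4, 4), dtype=np.uint16), dpi=0.0)
    scan = FilmScan(np.zeros((3, 4, 5), dtype=np.uint16), dpi=72.0)
    assert scan.spacing_mm == pytest.approx(25.4 / 72)
    assert scan.shape == (4, 5)


def test_dose_map_flag_shape_checked():
    with pytest.raises(ValueError):
        DoseMap(np.zeros((4, 4)), 0.35, flagged=np.zeros((2, 2), dtype=bool))
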
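# Methods

This note records the models behind `filmdose`, the parameter choices that
matter, the numerical details, and what the synthetic test bench does and
does not establish about real film.

## Dose-response model

Radiochromic film darkens with absorbed dose; on a flatbed scanner in
transmission mode the normalized pixel value of each color channel falls
monotonically from near 1 (clear film) toward an asymptote. We model the
response of channel k of one production lot as the rational function

    X_k(D) = a_k + b_k / (D − c_k),      b_k > 0,  c_k < D_min,

on a stated dose domain (default 0–400 cGy). The pole c_k lies below the
domain, so X_k is finite, strictly decreasing, and invertible in closed
form. The equivalent saturating parameterization A + B·D/(D+C) maps to the
same family via (a, b, c) = (A+B, −BC, −C); fitting is therefore always done
in the standard parameterization and converted on request.

*Response definition.* "Response" is the trimmed mean (central 80%) of
normalized 16-bit pixel values over a rectangular ROI — a dimensionless
transmission-like value in (0, 1]. The trim makes strip readings robust to
edge artifacts and dust without biasing a uniform region.

*Fitting.* With exactly three distinct doses the coefficients solve a 3×3
system exactly (pairwise elimination leaves a linear equation in the pole).
With four or more, Levenberg–Marquardt least squares on the response
residuals is initialized from the exact solve of the lowest/middle/highest
dose triple, removing any initialization sensitivity; tolerances are set to
1e-14 so the optimizer runs to numerical convergence. Fits whose pole lands
inside the dose domain or whose response is not strictly decreasing are
rejected with an error, never returned.

## One-scan session rescaling

Scanner electronics, scan temperature and time-after-exposure shift the
absolute response; across scanners of the same family the shift is well
described per channel by an affine map. Given a published generic curve
N(D) and the measured responses X₁ (unexposed) and X₂ (dose D₂) of two
reference strips from the same lot, the session curve is X(D) = α + β·N(D)
with (α, β) the unique solution of the two-point linear system. Because the
rational family is closed under affine maps of the response (a → α + βa,
b → βb, pole unchanged), the session curve inherits all curve invariants or
the rescale is rejected.

Two consequences are load-bearing and tested: (i) for *any* affine
perturbation of the response the rescaled reconstruction is exact on
noiseless data — this is the protocol's correctness claim; (ii) the session
curve passes exactly through both reference readings.

The reference dose defaults to 160 cGy, chosen near the highest dose on the
application film, where the curve still has useful slope in all channels.
The timing rule is enforced as stated: exposure window t requires an
exposure-to-scan delay of at least 4t (dose error from post-exposure
darkening < 0.5%); the darkening kinetics themselves are not modeled.

## Triple-channel reconstruction

Per pixel, the three channel responses are modeled as x_k = (1+Δ)·X_k(D)
with a single dose D and a single multiplicative disturbance Δ capturing
film-thickness variation and similar dose-independent effects. The
estimate minimizes F(D, Δ) = Σ_k [x_k − (1+Δ)X_k(D)]² subject to D in the
dose domain and |Δ| ≤ 0.1 (config). The disturbance is profiled out in
closed form, Δ(D) = Σ x_k X_k(D) / Σ X_k(D)² − 1 (clipped), leaving a 1-D
problem in D solved by a dense grid (0.5 cGy step; ties toward the smaller
dose) plus vectorized golden-section refinement to 0.001 cGy, so reported
doses are accurate to well under 0.01 cGy relative to the continuum
minimizer. The solver is fully deterministic.

The disturbance is applied to the *measured* response (the (1+Δ) factor
multiplies the model prediction to match x); attaching it to the prediction
instead differs only at second order in Δ. Channels are unweighted in the
sum; sensitivity weighting would be a straightforward extension.

Identifiability rests on the three channels having genuinely different
curve shapes: a common multiplicative factor moves the triplet along the
(X_R, X_G, X_B) ray, while a dose change moves it along the curve's
tangent; these directions are well separated for realistic lot curves
except at very high dose, where all channels flatten and dose noise grows.

*Scan pre-filtering.* Film-QA practice filters scanned images before dose
conversion to suppress pixel noise and film grain. `smooth_scan` applies a
per-channel Gaussian of σ = 1 pixel (~0.35 mm at 72 dpi), the default in
the QA workflow. At 240 cGy, where channel sensitivity is lowest, raw pixel
noise of 0.002 response units otherwise maps to ~6 cGy of per-pixel dose
noise; the filter cuts this several-fold while displacing penumbra shapes
by far less than the 3 mm distance criterion. Single-pixel analyses
(reference-strip ROIs, the solver API) are unaffected.

## Gamma comparison

Gamma at dose tolerance 3% and distance-to-agreement (DTA) 3 mm, with the
dose tolerance taken globally as a percentage of the reference (plan)
maximum — the convention of film-QA software of this protocol's era; a
fixed normalization dose is configurable. Pixels whose plan dose is below
10% of the normalization dose are excluded from the passing fraction (the
threshold is configurable because pass rates depend on it).

The reference, not the measurement, is interpolated (bilinear). The
minimization searches rings of increasing radius around each measured
pixel; the radial step is the pixel spacing divided by
`interp_subdivisions` (default 10), with matching angular density, capped
at `search_radius_factor` × DTA (default 3). Since any candidate at
distance s contributes at least (s/dta)², a pixel's minimum is final once
the ring distance alone exceeds its current best — the search
self-terminates and equals an exhaustive all-pairs evaluation at the same
sampling resolution (verified against a brute-force oracle). An optional
`max_gamma` cap stops refining pixels already known to fail; reported
values above the cap are lower bounds, and the passing fraction is exact
for any cap ≥ 1. Resampling between grids assumes both maps place (0,0) mm
at the top-left pixel center.

## The simulator

The simulator inverts the measurement chain so that every claim about the
analysis can be checked against known ground truth:

    pixel_k = round(65535 · [gain_k · X_k(D) · (1 + Δ(r)) + offset_k + ε]),

with ε ~ N(0, noise_sd) i.i.d. per pixel and Δ(r) a Gaussian-smoothed white
noise field scaled to a stated peak amplitude (default correlation length
10 mm). Scanner differences between "facility A" (identity) and "facility
B" are per-channel affine response transforms — exactly the model class the
One-scan rescale corrects. Facility B's defaults, gain (0.97, 0.97, 0.98)
and offset (+0.02, +0.02, +0.015), produce dose errors of ~4% at 80 cGy
rising to ~9% at 240 cGy when facility A's calibration is applied without
rescaling.

*Lot curves.* The simulated lot uses (a, b, c) of (0.18, 40, −50) for red,
(0.30, 45, −65) for green and (0.50, 25, −55) for blue on 0–400 cGy: red
the most sensitive at low dose, blue the least, all responses starting near
1 — the qualitative sensitivity ordering of real radiochromic film.

*Study conditions.* The headline simulation uses a 200×200-pixel frame at
72 dpi (0.3528 mm spacing), calibration strips at 0/80/160/320 cGy,
reference strips at 0/160 cGy, pixel noise sd 0.002, and a disturbance
field of peak amplitude 0.02 on the application film.

*Plan pattern.* The three-level test pattern (80/160/240 cGy on a 10 cGy
bath) consists of nested smooth-edged superelliptical regions, the 240 cGy
boost forming a broad central core surrounded by thinner 160 and 80 cGy
shells, with 2 mm Gaussian edge smoothing for penumbra-like gradients and
seed-jittered centers. The boost-dominant sizing mirrors a dose-painting
prescription and serves a methodological purpose: the gamma test can only
detect a systematic dose error on plateaus wider than the DTA scale — on a
plan dominated by penumbra, a nearby penumbra dose always rescues a wrong
plateau value, and the comparison becomes insensitive by construction. With
this pattern the cross-scanner no-protocol scenario fails roughly 40% of
evaluated pixels (passing rate ~57%), while both One-scan scenarios pass at
essentially 100%, independent of the pattern geometry.

*What the simulator omits.* Post-exposure darkening kinetics, lateral
flatbed response (position-dependent gain), dose-rate and beam-energy
dependence, film grain structure beyond i.i.d. Gaussian pixel noise, and
scanner saturation behavior other than hard clipping at the 16-bit range.
Passing tests therefore establish the correctness of the analysis chain
under the affine-scanner/multiplicative-disturbance model, not the physical
fidelity of that model for any particular scanner pair; the real-film
analogue of the cross-scanner collapse is matched qualitatively, not pixel
for pixel.

## Numerical details and edge cases

- Doses at the curve pole or outside the domain raise errors; map-level
  inversion clamps out-of-range responses to the domain boundary and flags
  the pixels instead (the flags propagate to the dose map).
- All-zero pixel triplets are invalid (NaN + flag in maps, error in the
  scalar API). Solver minima on the dose-domain boundary are flagged; more
  than 5% flagged pixels logs a warning.
- Dose planes are exchanged as plain text with a rows/cols/spacing header
  at two decimal places (0.005 cGy round-trip accuracy); calibration
  coefficients round-trip exactly via `repr` formatting.
- Determinism: all simulator randomness flows from explicit integer seeds
  (default 20140129); reconstruction and gamma are deterministic, so
  identical inputs give bit-identical maps.
- The acceptance script runs the full 200×200 study; the test suite runs
  the same three scenarios at the same size (about a minute in total) plus
  unit and property tests at smaller frames.

## Known limitations

- The affine scanner model is the correction's own model class; scanners
  with nonlinear response differences would leave a residual the protocol
  cannot remove (and the simulator cannot currently generate them).
- Global-maximum gamma normalization makes low-dose errors easy to pass;
  local-normalization gamma is not implemented.
- No multi-scan averaging, no lateral scanner correction, no DICOM-RT
  import; plan grids arrive as text matrices.
- The 1-pixel pre-filter trades a small amount of spatial resolution for
  dose noise; analyses of sub-millimeter structure should disable it.
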
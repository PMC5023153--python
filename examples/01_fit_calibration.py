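"""Fit per-channel calibration curves from simulated film strips.

Renders the standard exposure series -- an unexposed strip plus strips at
80, 160 and 320 cGy -- on a noisy scanner, extracts trimmed-mean ROI
responses, and fits the rational curve X(D) = a + b/(D - c) per channel.
The fitted coefficients should match the simulator's lot curves closely.
"""

from filmdose import (
    CALIBRATION_DOSES,
    default_lot_curves,
    fit_generic_from_strips,
    reference_scanner,
    render_strip_set,
)

lot = default_lot_curves()
scanner = reference_scanner(noise_sd=0.002, seed=101)
strips = render_strip_set(list(CALIBRATION_DOSES), lot, scanner)
fitted = fit_generic_from_strips(strips, list(CALIBRATION_DOSES),
                                 lot_id=lot[0].lot_id)

print(f"calibration doses: {[int(d) for d in CALIBRATION_DOSES]} cGy")
print(f"{'ch':>3} {'a (fit)':>9} {'a (true)':>9} {'b (fit)':>9} "
      f"{'b (true)':>9} {'c (fit)':>9} {'c (true)':>9}")
for fit, true in zip(fitted, lot):
    print(f"{fit.channel.value:>3} {fit.a:9.5f} {true.a:9.5f} "
          f"{fit.b:9.3f} {true.b:9.3f} {fit.c:9.2f} {true.c:9.2f}")
print("\nEach row is one color channel; with 0.002 response noise the")
print("fitted coefficients sit within a fraction of a percent of the")
print("generating lot curve, which is what makes the curve publishable.")
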
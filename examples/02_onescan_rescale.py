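"""Adapt a published calibration to a different scanner with One-scan.

A second facility's scanner reports different absolute responses (here a
per-channel affine perturbation: ~3% gain, +0.02 offset).  Two reference
strips -- unexposed and 160 cGy -- scanned together with the film are
enough to recover that perturbation exactly and rescale the published
curve.  The example prints the dose error at 160 cGy with and without the
protocol.
"""

from filmdose import (
    default_lot_curves,
    facility_b_scanner,
    invert_response,
    render_strip_set,
    rescale_curves_from_strips,
)
from filmdose.calibration import eval_response

lot = default_lot_curves()
scanner_b = facility_b_scanner(noise_sd=0.0, seed=202)
ref_low, ref_high = render_strip_set([0.0, 160.0], lot, scanner_b)
session = rescale_curves_from_strips(lot, ref_low, ref_high)

print(f"{'ch':>3} {'gain':>6} {'offset':>7} {'raw dose err':>13} "
      f"{'rescaled err':>13}   (true dose 160 cGy)")
for k, (generic, rescaled) in enumerate(zip(lot, session)):
    measured = scanner_b.gain[k] * eval_response(generic, 160.0) + scanner_b.offset[k]
    raw = invert_response(generic, measured) - 160.0
    fixed = invert_response(rescaled, measured) - 160.0
    print(f"{generic.channel.value:>3} {scanner_b.gain[k]:6.2f} "
          f"{scanner_b.offset[k]:7.3f} {raw:10.2f} cGy {fixed:10.4f} cGy")
print("\nWithout rescaling the foreign calibration misreads 160 cGy by")
print("5-10 cGy depending on the channel; after the two-point One-scan")
print("rescale the error collapses to the 0.01 cGy level.")
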
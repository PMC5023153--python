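"""Separate dose from film-thickness disturbance with three channels.

Renders a noiseless scan of a uniform 160 cGy film carrying a smooth 3%
multiplicative thickness-like disturbance, then reconstructs per pixel the
dose D and the disturbance Delta jointly by least squares over the three
color channels.  A single channel cannot tell the disturbance from a dose
change; three channels with different dose sensitivities can.
"""

import numpy as np

from filmdose import (
    default_lot_curves,
    reference_scanner,
    render_scan,
    single_channel_dose,
    triple_channel_dose,
)
from filmdose.simulate import PhantomPlan

lot = default_lot_curves()
plan = PhantomPlan(np.full((80, 80), 160.0), spacing_mm=25.4 / 72)
scan = render_scan(plan, lot, reference_scanner(seed=303),
                   disturbance_amplitude=0.03, disturbance_corr_mm=8.0)

dose3, delta = triple_channel_dose(scan, lot)
dose1 = single_channel_dose(scan, lot[0], "R")

rms3 = float(np.sqrt(np.mean((dose3.dose - 160.0) ** 2)))
rms1 = float(np.sqrt(np.mean((dose1.dose - 160.0) ** 2)))
print(f"true dose field:            uniform 160 cGy")
print(f"disturbance field:          smooth, peak |Delta| = 0.03")
print(f"red-channel-only dose RMS:  {rms1:6.2f} cGy")
print(f"triple-channel dose RMS:    {rms3:6.2f} cGy")
print(f"recovered Delta range:      [{np.nanmin(delta.delta):+.4f}, "
      f"{np.nanmax(delta.delta):+.4f}]")
print("\nThe single channel converts the 3% thickness variation into a")
print("dose error of a couple of cGy RMS; the triple-channel solve")
print("absorbs it into Delta and reproduces the flat field almost exactly.")
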
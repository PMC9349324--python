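"""Bennett ocular-magnification correction in isolation.

Shows how the physical scan length, the mm/pixel scale and the annulus
pixel count change with axial length, and that the *physical* area of the
analysis annulus stays constant — which is the point of the correction.
"""

import numpy as np

from octaquant import AnnulusSpec, EyeBiometry, annulus_mask, bennett_actual_scan_length, pixel_scale

print(f"{'AL (mm)':>8s} {'scan (mm)':>10s} {'mm/px':>9s} {'annulus px':>11s} {'area (mm^2)':>12s}")
for al in np.linspace(22.0, 26.0, 5):
    s = bennett_actual_scan_length(EyeBiometry(al))
    scale = pixel_scale(s, 245)
    mask = annulus_mask((245, 245), AnnulusSpec(), scale)
    print(f"{al:8.2f} {s:10.3f} {scale:9.5f} {mask.sum():11d} {mask.sum() * scale**2:12.3f}")

print(
    "\nShorter eyes image a smaller retinal patch per scan, so the fixed"
    " 1.0-2.5 mm annulus covers more pixels; the physical area stays at"
    " pi*(1.25^2-0.5^2) = 4.123 mm^2 for every eye."
)
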
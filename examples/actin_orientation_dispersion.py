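"""Quantify F-actin fiber organisation from a synthetic phalloidin image.

Renders fibers concentrated around 20 degrees from vertical (von Mises
kappa = 4 on doubled angles), estimates per-pixel orientation with the
structure tensor, and prints the dispersion statistic: 0 deg for
perfectly parallel fibers, ~40.5 deg for an isotropic network. Lower
dispersion means better-aligned stress fibers.
"""

import numpy as np

from ermech_quant import cytoskeleton as cs
from ermech_quant import synthetic

img, angles, _ = synthetic.gen_fiber_image(
    n_fibers=30, mean_angle_deg=20.0, concentration=4.0, seed=2
)
ch = img.channel("F-actin")
field = cs.orientation_field(ch, np.ones(ch.shape, bool), tensor_sigma_px=2.0)

disp = cs.dispersion(field, weighting="coherence")
truth_disp = cs.axial_dispersion(angles)
dens = cs.intensity_density(ch, np.ones(ch.shape, bool), img.pixel_size_nm)

print(f"fibers drawn: {len(angles)}, mean orientation 20 deg from vertical")
print(f"pixel-level dispersion:  {disp:.2f} deg")
print(f"fiber-truth dispersion:  {truth_disp:.2f} deg "
      f"(uniform-network maximum {cs.MAX_DISPERSION_DEG:.2f} deg)")
print(f"intensity density: {dens['per_px']:.1f} a.u./px = "
      f"{dens['per_um2']:.0f} a.u./um^2")
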
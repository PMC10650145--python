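"""Generate a synthetic forearm cube and inspect the vessel signature.

Builds a 64x64 cube with 250 bands (400-1000 nm) for a light-brown skin
preset, then compares mean brightness inside vs outside the vessel mask at
the 740 nm absorption dip and at a dip-free visible band.
"""

import numpy as np

from veinindex import SkinSimConfig, band_at, generate_sample

sample = generate_sample(SkinSimConfig(skin_type="light_brown", seed=7))
cube, mask = sample.cube, sample.mask

print(f"cube: {cube.values.shape}, axis {cube.wavelengths_nm[0]:.0f}-"
      f"{cube.wavelengths_nm[-1]:.0f} nm, vessel pixels: {mask.n_vessel_pixels}")

for target in (500.0, 740.0):
    layer = band_at(cube, target)
    inside = layer.values[mask.values].mean()
    outside = layer.values[~mask.values].mean()
    print(f"band {layer.center_wavelength_nm:6.1f} nm: vessel mean {inside:.4f}, "
          f"skin mean {outside:.4f}, ratio {inside / outside:.3f}")

# Vessels absorb at the planted 740 nm dip (ratio well below 1) but are
# nearly invisible at 500 nm, where only spatial blur bleeds through —
# which is why single-band separation is a weak vessel detector.
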
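"""Evaluate the published three-wavelength vessel index on a synthetic cube.

II = (I714 - I738) * (I714 - I882) / (I714 + I738 + I882)

Prints the masked RMS of the normalized index image against the ground-truth
vessel mask — lower is better, 0 would mean every vessel pixel sits exactly
at the ideal (dark or bright) value.
"""

from veinindex import (
    SkinSimConfig,
    eval_vessel_index,
    generate_sample,
    masked_rms,
    normalize_index,
)

sample = generate_sample(SkinSimConfig(skin_type="fair", seed=7))
img = eval_vessel_index(sample.cube)
print(f"index image: {img.values.shape}, realized band centers "
      f"{tuple(round(c, 1) for c in img.band_centers_nm)} nm")

score = masked_rms(normalize_index(img), sample.mask)
print(f"masked rms: {score.rms:.4f} ({score.polarity}, "
      f"{score.n_pixels_scored} vessel pixels scored)")

# The published parameters were tuned on real forearm spectra; on this
# synthetic phantom they are a reasonable but not optimal starting point —
# run 03_formula_search.py to see what an exhaustive search finds instead.
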
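"""Compute the 14 pattern indices for one region.

Runs the full single-region pipeline (binarize -> extract spots ->
indices) on a synthetic head region and compares the key indices with the
generator's ground truth.
"""

from pattquant import binarize, compute_indices, extract_spots
from pattquant.indices import INDEX_NAMES
from pattquant.synth import SyntheticSpec, generate_pattern, render_image

spec = SyntheticSpec(seed=8, body_part="HD", shape=(150, 170))
truth_pattern, truth = generate_pattern(spec)
image = render_image(truth_pattern, spec)

pattern = binarize(image)
spots = extract_spots(pattern, image)
idx = compute_indices(spots, pattern, image)

print(f"spots: {spots.n_all} total, {spots.n_interior} interior, "
      f"qualifying = {spots.qualifying}")
for name in INDEX_NAMES:
    print(f"  {name:4s} = {getattr(idx, name):10.5f}")
print(f"truth: SA = {truth['mean_area_cm2']:.5f} cm^2, "
      f"EE = {truth['mean_axis_ratio']:.3f}, "
      f"PL = {truth['wavelength_cm']:.4f} cm")
# SS/SA describe spot size (cm / cm^2), EE and EL spot shape, PL and MD
# the characteristic spacing between spots, FM the melanistic fraction,
# SI the darkness of the spots; the *D variants are the spreads across
# spots within this one region.
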
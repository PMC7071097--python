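"""Local pattern spectrum of a patch containing a bright lesion.

Builds the opening/closing pyramids (disc SEs, sizes 0,2,...,22) over a
synthetic image, extracts the signed granulometric curve of one exudate
patch and prints where the bright-structure mass concentrates.
"""

import numpy as np
from scipy import ndimage as ndi

from retipatch.granulometry import SEFamily, build_pyramid, pattern_spectrum_local
from retipatch.synthetic import SyntheticConfig, generate_sample

sample = generate_sample(SyntheticConfig(rng_seed=5, noise_sigma=0.0))
green = sample.image[..., 1]

se = SEFamily(shape="disc", step=2, nmax=22)
pyr_open = build_pyramid(green, "opening", se)
pyr_close = build_pyramid(green, "closing", se)
print(f"pyramids built: {pyr_open.n_levels} levels each (sizes {se.sizes.tolist()})")

labels, _ = ndi.label(sample.bright_mask)
cy, cx = (int(v) for v in ndi.center_of_mass(labels == 1))
bounds = (max(0, cy - 32), max(0, cx - 32), 64, 64)
ps = pattern_spectrum_local(pyr_open, pyr_close, bounds)

print("signed pattern spectrum (closings at negative sizes, openings positive):")
for size, value in zip(ps.sizes, ps.values):
    bar = "#" * int(round(400 * value))
    print(f"  n={size:+3d}  {value:.5f} {bar}")

half = len(ps.sizes) // 2
pos_sizes = ps.sizes[half + 1:]
small = pos_sizes <= 10
peak = pos_sizes[small][int(np.argmax(ps.positive[small]))]
print(
    f"\nSmall-scale bright mass peaks at SE size {peak}: the first disc larger\n"
    "than the lesion removes it from the opening pyramid, so the volume lost\n"
    "between those levels spikes — that location encodes the lesion's size.\n"
    "The rising tail toward n=22 is the smooth background/vignette, which only\n"
    "the largest discs start to erode."
)
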
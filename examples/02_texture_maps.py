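"""Quantize a volume and extract sliding-cube Haralick feature maps.

Shows the full preprocessing of one subject: histogram equalization to 16
grey levels, then per-cube GLCM energy and entropy maps, and how the
boundary-shell energy separates a smooth-boundary from a sharp-boundary
volume.
"""

import numpy as np

from braintexture.quantize import equalize_histogram
from braintexture.synthetic import generate_brain_volume
from braintexture.texture import texture_feature_maps

for name, smoothness in (("sharp boundaries (VisDys- analogue)", 0.3),
                         ("smooth boundaries (VisDys+ analogue)", 2.0)):
    vol = generate_brain_volume((40, 40, 40), smoothness=smoothness,
                                folding_amplitude=2.0, noise_sd=0.05, seed=7)
    q = equalize_histogram(vol, n_levels=16)
    hist = np.bincount(q.levels[q.brain_mask], minlength=16)
    maps = texture_feature_maps(q, cube_size=5, stride=1,
                                features=("energy", "entropy"))
    energy, entropy = maps["energy"], maps["entropy"]
    print(name)
    print(f"  equalized level histogram spread: "
          f"{hist.min()}-{hist.max()} voxels per level "
          "(flat = well equalized)")
    print(f"  valid cube positions: {energy.valid_mask.sum()} "
          f"of {energy.valid_mask.size}")
    print(f"  mean in-brain energy  {np.nanmean(energy.values):.4f}   "
          f"mean entropy {np.nanmean(entropy.values):.4f}")

print("\nEnergy (sum of squared GLCM entries) is higher where local texture "
      "is uniform;\nblurring the tissue boundaries raises it while entropy "
      "falls — the contrast\nthe classifier will exploit.")
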
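"""Clean one image and tile it into patches.

The cleaning pipeline resamples to a fixed resolution, denoises with
adaptive non-local means, removes non-skin background with an Otsu
threshold mask, and min-max normalizes intensities to [0, 1]. Patching then
tiles the result into 32x32 tiles, the unit the patch classifier scores.
"""

import numpy as np

from dermapatch import (PreprocessConfig, preprocess_image, extract_patches,
                        patch_coverage, SynthConfig, generate_cohort)

sample = generate_cohort(SynthConfig(n_images=1, prevalence=1.0, seed=3))[0]

clean = preprocess_image(sample.image, PreprocessConfig(target_size=(128, 128)))
print(f"cleaned image: {clean.pixels.shape}, range "
      f"[{clean.pixels.min():.2f}, {clean.pixels.max():.2f}], "
      f"recorded I_min={clean.i_min:.3f} I_max={clean.i_max:.3f}")
print("steps applied:", " -> ".join(clean.steps))

grid = extract_patches(clean, 32, 32)
print(f"non-overlapping tiling: {grid.count} patches "
      f"(= floor(128/32)^2 = {(128 // 32) ** 2})")

overlap = extract_patches(clean, 32, 16)
cover = patch_coverage(overlap)
print(f"overlapping (stride 16): {overlap.count} patches; "
      f"an interior pixel is covered by {cover[64, 64]} of them")
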
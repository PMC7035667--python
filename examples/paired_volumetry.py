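"""Paired CE-vs-FLAIR volumetry on phantom segmentation masks.

Non-enhanced FLAIR imaging systematically under-segments synovium
relative to contrast-enhanced T1 imaging. This script generates CE/FLAIR
mask pairs at a known volume ratio for a few synthetic patients,
measures the volumes, and runs the paired comparison (percent
difference, Pearson r, paired t-test).
"""

import numpy as np

from synovaquant import PhantomConfig, generate_paired_masks, mask_volume, paired_compare

rng = np.random.default_rng(7)
pairs = []
for patient in range(6):
    # each synthetic knee gets its own grid size and FLAIR/CE ratio
    nx = int(rng.integers(18, 30))
    config = PhantomConfig(grid_shape=(nx, 20, 10))
    ratio = rng.uniform(0.75, 0.9)
    mask_ce, mask_flair, achieved = generate_paired_masks(config, ratio)
    v_ce = mask_volume(mask_ce, config.voxel_size)
    v_fl = mask_volume(mask_flair, config.voxel_size)
    pairs.append((v_ce, v_fl))
    print(f"patient {patient}: CE {v_ce:.3f} cm3, FLAIR {v_fl:.3f} cm3, "
          f"achieved ratio {achieved:.3f}")

res = paired_compare(pairs)
print()
print(f"mean percent difference (FLAIR denominator): "
      f"{res.percent_diff_mean:.1f}% +/- {res.percent_diff_sd:.1f}%")
print(f"Pearson r = {res.pearson_r:.3f}, paired t({res.df}) = "
      f"{res.t_statistic:.2f}, p = {res.p_value:.2g}")
print()
print("positive percent differences mean FLAIR volumes run smaller than CE;")
print("r close to 1 says the two sequences still rank patients identically.")
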
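"""CT preprocessing pipeline: window, crop to organ slices, resample.

Builds a synthetic raw CT-like volume in Hounsfield units with an
ellipsoidal "lung" mask, and runs the full input pipeline down to the
model's 144x144x48 grid.
"""

import numpy as np

from symfenet import crop_slices_by_mask, normalize_ct, resample_to

rng = np.random.default_rng(0)
raw = rng.normal(-700.0, 150.0, size=(96, 96, 64))   # air-dominated chest
raw[30:70, 30:70, 20:50] += 600.0                    # soft-tissue block
raw[10, 10, 10] = -3000.0                            # out-of-window voxel

mask = np.zeros(raw.shape, dtype=bool)
mask[20:80, 20:80, 18:52] = True                     # lung occupies z 18..51

print(f"raw volume {raw.shape}, range [{raw.min():.0f}, {raw.max():.0f}] H.U.")
v = normalize_ct(raw)
print(f"after CT window [-2050, 950] -> [-1, 1]: "
      f"range [{v.min():.2f}, {v.max():.2f}]")
v = crop_slices_by_mask(v, mask)
print(f"after dropping lung-free axial slices: {v.shape} "
      f"({mask.any(axis=(0, 1)).sum()} slices kept)")
v = resample_to(v)
print(f"after trilinear resampling: {v.shape} (model input grid)")
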
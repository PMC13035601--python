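"""LR fusion geometry: how mirrored voxel pairs are aligned.

Builds a tiny volume with a marked voxel on the left side, forms the LR
fusion volume at several shifts, and shows where the mirror partner lands.
"""

import numpy as np

from symfenet import ShiftParam, make_lr_fusion, mirror_index

W = 8
v = np.zeros((W, 4, 4, 1), dtype=np.float32)
v[2, 1, 1, 0] = 1.0          # a "lesion" voxel on the left
v[mirror_index(2, W), 1, 1, 0] = 2.0  # its mirror partner on the right

print(f"volume width {W}: marked voxel at x=2 (value 1), "
      f"mirror partner at x={mirror_index(2, W)} (value 2)\n")

for shift in [(0, 0, 0), (1, 0, 0), (0, 1, 0)]:
    fused = make_lr_fusion(v, ShiftParam(*shift)).data
    x, y, z = np.unravel_index(np.argmax(fused[..., 1]), fused[..., 1].shape)
    print(f"shift {shift}: fusion shape {fused.shape}; "
          f"mirrored channel peaks at (x={x}, y={y}, z={z}) "
          f"value {fused[x, y, z, 1]:.0f}")

zero = make_lr_fusion(v).data
print("\nWith the zero shift the pair (1, 2) occupies one location across "
      "the two channels:")
print("channel 0 (left half) at x=2:", zero[2, 1, 1, 0])
print("channel 1 (mirrored right half) at x=2:", zero[2, 1, 1, 1])
print("A 3x3x3 convolution over the fusion volume therefore sees each "
      "voxel and its mirror partner in the same receptive field.")
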
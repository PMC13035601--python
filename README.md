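# symfenet

Left-right relationship-aware classification of 3D medical volumes.

Human anatomy is roughly mirror-symmetric about the mid-sagittal plane, and
several imaging findings are defined by how they respect or break that
symmetry: ground-glass opacities in COVID-19 chest CT are typically
bilateral, many focal brain lesions are unilateral.  A generic 3D CNN has
to discover this structure from data; `symfenet` builds it in.

**Who this is for:** researchers in medical image analysis who want a
transparent, fully seeded reference implementation of symmetric feature
extraction — either to classify volumes whose discriminative signal is
bilateral (a)symmetry, or to study the mechanism itself on controlled
synthetic data.

## The model

A volume `V ∈ R^{W×H×D×C}` has its left-right axis on axis 0, with the
mirror plane between voxel columns `W/2−1` and `W/2`.

A **SymFE block** (symmetric feature extraction) with integer shift
`(s_w, s_h, s_d)`:

1. splits `V` at the mirror plane, flips the second half, shifts it by
   `(s_w, s_h, s_d)`, and stacks it on the channel axis — the *LR fusion
   volume* `Ṽ ∈ R^{W/2×H×D×2C}`, where each location holds a voxel and its
   mirror partner;
2. applies a 3×3×3 convolution with `K` kernels, ReLU, and 3D spatial
   dropout, giving `F̃ ∈ R^{W/2×H×D×K}`;
3. unfolds back to full width as `[F̃, flip(F̃)]` — every block output is
   exactly mirror-symmetric.

A **MultiSymFE module** runs SymFE blocks for every shift in a grid
(1 + 8·(max_offset/step) shifts: 33/25/17/9/1 for max offsets 8/6/4/2/0 at
step 2, s_d = 0) in parallel, absorbing patient-positioning gaps between
true LR correspondences, and fuses the `I` feature volumes by split
attention:

    s_{i,c} = (1/WHD) Σ_{x,y,z} F_i(x,y,z,c)
    a_{i,c} = 1 / (1 + exp(−s_{i,c}))
    O_c     = Σ_i a_{i,c} · F_{i,c}

The classifier stacks MultiSymFE modules with growing `K`, max pooling
between stages, and a global-average-pool + dense two-class head.

The package also provides the matching preprocessing (CT window
normalization −2050..950 H.U. → [−1, 1], MR percentile normalization,
mask-based axial slice cropping, resampling to 144×144×48), a synthetic
bilateral-phantom generator with controllable positional jitter, a seeded
cross-validated training harness, and a shift-matched plain-CNN control.
Everything is NumPy (+ numba kernels); there is no GPU dependency, and
eval-mode inference is bit-reproducible.

## Worked example

`examples/03_train_synthetic.py` generates 120 labeled phantoms
(bilateral vs unilateral lesions, 32×32×12 voxels), trains a compact
9-shift model, and evaluates on a held-out split (about three minutes on
one CPU):

```
$ python examples/03_train_synthetic.py
training grid-9 model (38156 parameters) on 90 phantoms...
loss per epoch: ['0.682', '0.629', '0.518', '0.395', '0.367', '0.255',
'0.372', '0.300', '0.132', '0.249', '0.208', '0.187', '0.236', '0.287']

held-out accuracy on 30 phantoms: 0.90 (chance = 0.50)
```

The loss falls as the blocks learn filters that compare each voxel with
its mirror partner; held-out accuracy well above 0.5 shows the model
recovered the left-right asymmetry rule that defines the classes.  The
other examples walk through the fusion geometry (`01`), the attention
weights (`02`), and the preprocessing pipeline (`04`).

A thin CLI wraps the same API:

```
symfenet simulate --n 200 --shape 48 48 16 --seed 7 --out data/
symfenet train --data data/ --grid 9 --kernels 8,16 --epochs 12 --out report.json
symfenet predict --ckpt runs/ckpt --in volume.nii.gz
```

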
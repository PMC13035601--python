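# Methods

## The model

Human anatomy is approximately mirror-symmetric about the mid-sagittal
plane, and several findings this package targets are defined by how they
respect or break that symmetry: ground-glass opacities in COVID-19 chest CT
tend to be bilateral, while many focal lesions are unilateral.  The
classifier makes the left-right (LR) relationship an explicit part of
feature extraction instead of hoping a generic 3D CNN discovers it.

A volume is a rank-4 array `V ∈ R^{W×H×D×C}` whose axis 0 is the body's LR
axis.  The mirror plane sits between voxel columns `W/2−1` and `W/2`, so
the mirror partner of column `x` is column `W−1−x` exactly, with no
interpolation; `W` must be even, and the preprocessing guarantees it.

**SymFE block.**  One block performs:

1. *LR fusion.*  Split `V` at the mirror plane, flip the second half along
   the LR axis, translate it by an integer shift `(s_w, s_h, s_d)` (zero
   fill), and stack it on the channel axis.  The result
   `Ṽ ∈ R^{W/2×H×D×2C}` holds each voxel and its (shifted) mirror partner
   at the same location.
2. *Feature extraction.*  A 3×3×3 convolution with `K` kernels and "same"
   zero padding over the fused channels, followed by ReLU and 3D spatial
   dropout (probability `p`, whole channels, train mode only).  A 3×3×3
   receptive field on the fusion volume sees a voxel's neighbourhood
   *and* its mirror neighbourhood jointly, which is what makes asymmetry
   locally detectable by a linear filter.
3. *Unfold.*  Concatenate the half-width features with their own LR flip,
   `[F̃, flip(F̃)]`, restoring width `W`.  Every block output is therefore
   exactly mirror-symmetric — a structural invariant the tests assert
   bitwise.

**MultiSymFE module.**  Patient positioning varies, so true LR
correspondences are displaced by a few voxels.  A module runs one SymFE
block per shift in an integer grid expanded from
`{(0,0,0)} ∪ {(±k,0,0)} ∪ {(0,±k,0)} ∪ {(±k,±k,0)}`, `k ∈ {step, …,
max_offset}` — 33/25/17/9/1 blocks for max offsets 8/6/4/2/0 at step 2.
Shifts along z are off by default because target volumes are shallow along
z.  The `I` feature volumes are fused by split attention:

    s_{i,c} = mean over (x,y,z) of F_i(x,y,z,c)
    a_{i,c} = σ(s_{i,c})
    O_c     = Σ_i a_{i,c} · F_{i,c}

The attention is the per-entry logistic sigmoid, deliberately *not*
normalized across blocks; a softmax-across-blocks variant exists behind
`normalize_across_blocks` (off by default) for comparison with the split
attention literature it descends from.  The fusion has no learnable
parameters.  Whether blocks share convolution weights is configurable;
the default is independent weights per block.

**Classifier.**  `[MultiSymFE(K_j) → BatchNorm → MaxPool(2)] × stages →
global average pool → BatchNorm → Dense(2)`, trained with softmax
cross-entropy.  The stage count and K schedule are this package's own
choices (the module, not the macro-architecture, is the mechanism under
test); the default is three stages with K = (16, 32, 64).  Config
validation guarantees the width stays even at every stage so the mirror
plane keeps falling between voxels.  A shift-matched plain-CNN control
with the same stage widths and pooling but ordinary full-width
convolutions (`build_control_cnn`) serves as the baseline.

Two classifier-assembly choices deserve explanation because they were
forced by experiment rather than taken from the architecture description:

* *Stage/head batch normalization* (`batch_norm=True`).  The fused feature
  volumes carry a large common-mode component (means ≈ 2, class-dependent
  variation ≈ 0.05 on the synthetic benchmark).  Without normalization,
  minibatch gradients at the head are dominated by common-mode noise and
  Adam cannot even recover the accuracy of a linear probe on frozen
  features; with per-channel standardization the same probe trains in a
  few dozen steps.  The SymFE block interior remains convolution + dropout
  only.
* *Zero-initialized head.*  The final dense layer starts at zero, so the
  model begins exactly at the chance predictor and early training is not
  spent undoing a large random head.

## Numerical engine

The layers are implemented directly in NumPy with hand-written adjoints,
which keeps every geometric rearrangement (split, flip, shift, unfold)
transparent to the brute-force voxel-correspondence oracles used in tests.
The 3×3×3 convolution has two interchangeable implementations — a
flat-offset formulation that turns each kernel tap into one contiguous
BLAS matmul, and numba direct kernels used for narrow channel counts —
both validated against `scipy.ndimage.correlate` and finite differences
(relative tolerance 1e-2 at float32).  Spatial dropout uses inverted
scaling (`1/(1−p)` at train time); evaluation mode is a pure function of
input and weights, and all randomness flows through explicit
`numpy.random.Generator` objects, so fixed seeds reproduce runs bitwise in
single-threaded execution.

## Preprocessing

* CT: clamp to [−2050, 950] H.U., map linearly to [−1, 1] (so −550 H.U. is
  exactly 0).
* MR: clip to the volume's [0.5, 99.5] percentiles, then z-score.  This is
  the clip-then-standardize reading of the nnU-Net-style normalization; a
  min-max-to-[0,1] mode is available (`mode="minmax"`) because the phrase
  "scaling to percentiles" is ambiguous between the two.
* Axial slices with no organ-mask foreground are dropped.  Organ masks are
  an input, not computed here: lung/infection segmentation is upstream
  prior work, and the synthetic generator fabricates masks.
* Resample trilinearly to exactly 144×144×48 (nearest-neighbour for
  masks).  Resampling ignores original voxel spacing by design — the model
  consumes a fixed grid — and linear interpolation guarantees no intensity
  overshoot.
* NIfTI volumes are reoriented to canonical (RAS) axes from header codes
  so axis 0 is always the LR axis.

## Synthetic phantoms

The generator produces the statistical structure the model exploits while
staying analyzable:

* background: a Gaussian-smoothed random field (smoothing σ 3 voxels,
  amplitude ≈ 0.3) made *exactly* mirror-symmetric by averaging with its
  own flip;
* lesions: 1–3 truncated-Gaussian spheres, radius 3–6 voxels, intensity
  offset Δ = 0.5, constrained strictly inside one half-volume.  Label 0
  (bilateral) adds every lesion together with its exact mirror; label 1
  (unilateral) does not.  Before noise and jitter a label-0 phantom
  satisfies `v == flip(v)` bitwise and a label-1 phantom violates it by
  exactly Δ at the lesion core;
* i.i.d. Gaussian voxel noise, σ = 0.1;
* rigid positional jitter applied last: in-plane rotation about z (uniform
  within ±θ_max) and integer in-plane translation (uniform within ±t_max),
  imitating patients rotated or displaced from the ideal supine position.
  Per-sample draws are recorded in the dataset manifest.

Default volume shape is 48×48×16.  The model-free asymmetry score
`mean |v − flip(v)|` separates the classes perfectly at σ = 0 and with
AUC ≥ 0.95 at the default noise, and increases monotonically with
translation jitter on label-0 phantoms — the positional gap the multi-shift
grid is designed to absorb.  What the phantoms do *not* model: CT/MR
physics, anatomical texture (airways, vessels, GGO texture), class
differences beyond symmetry and lesion mass.  Passing the synthetic
benchmark therefore demonstrates the mechanism — mirrored-pair feature
extraction and shift-tolerant fusion — not clinical performance.

## Training and evaluation

Adam, minibatch 8, linear warmup to a peak learning rate over the first
`warmup_epochs` (first epoch at `peak/warmup`), cosine decay to ~0 over
the remaining epochs; the reference recipe is peak 0.005, warmup 10, 80
epochs (lung) / 60 (brain), dropout 0.1.  Evaluation is stratified
four-fold cross-validation; accuracy, F1, precision and recall are
computed from the confusion matrix (zero-denominator ratios report 0 with
a `degenerate` flag) and reported per fold plus mean ± sample SD (ddof 1).
A two-sided t-test utility (paired and unpaired) is provided for
post-hoc comparisons.

Desk-scale benchmark runs use smaller problems than the reference recipe;
the suite's capability run trains the grid-9 model (K = 8, 16) on 400
48×48×16 phantoms for 16 epochs with peak learning rate 0.01 (warmup 2),
and the jitter ablation compares grids "9" and "1" on 32×32×12 phantoms
(48/class, K = 6, 12, 6 epochs, 4-fold CV, 3 seeds).  These sizes are the
package's choice of a small but informative benchmark; the learning-rate
schedule shape is unchanged.

## Degenerate inputs and tie-breaks

Odd-width volumes are rejected, never cropped (cropping would move the
mirror plane).  Shift magnitudes at or beyond the half-extent saturate to
an all-fill mirrored half inside blocks, so large grids remain usable on
small deep-stage volumes; the standalone `shift3d` rejects them.  Grid
ordering is lexicographic by (|s_w|+|s_h|+|s_d|, s_w, s_h, s_d) with the
zero shift first, fixing checkpoint and attention-log layout.  Max-pool
ties resolve to the first maximum (argmax order).  Constant MR volumes
(zero variance) are rejected rather than silently returning zeros.

## Known limitations

The engine is single-CPU NumPy: fine for desk-scale experiments and tests,
not for 144×144×48 volumes with the 33-block grid at full K — the
reference-scale configuration exists and type-checks but is not trained
here.  Sub-voxel shifts, learned symmetry-plane detection, and elastic
(non-rigid) jitter are out of scope.  Fold-level determinism assumes
single-threaded BLAS; multi-threaded BLAS may reorder reductions.
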
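"""Synthetic bilateral phantoms for training and benchmarking.

Each phantom is a smooth random background field made exactly
mirror-symmetric about the mid-sagittal plane, plus compact spherical
lesions of intensity offset delta:

* label 0 ("bilateral"): every lesion is added together with its exact LR
  mirror, so before noise and jitter the phantom satisfies
  ``v == flip_lr(v)`` bitwise;
* label 1 ("unilateral"): lesions are placed on one side only, violating
  mirror symmetry by delta at the lesion cores.

i.i.d. Gaussian voxel noise is added, then an optional rigid positional
jitter — in-plane rotation about the cranio-caudal axis plus integer
in-plane translation — imitating patients whose position deviates from the
ideal supine pose.  Jitter is what breaks the naive zero-shift mirror
correspondence; the multi-shift fusion grid exists to absorb it.  An
elliptical "organ" mask is generated alongside each phantom for the
slice-cropping pipeline.

Lesions have compact support (truncated Gaussian) and are kept strictly
inside one half-volume, so the pre-noise asymmetry of a unilateral phantom
is exactly delta at the lesion peak — the model-free asymmetry statistic
separates the classes by construction, which is what makes the benchmark's
labels learnable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, rotate

from .geometry import ShiftParam, flip_lr, shift3d

__all__ = ["PhantomSpec", "LabeledDataset", "generate_phantom",
           "asymmetry_statistic", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters.

    Units: spatial quantities in voxels, angles in degrees, intensities in
    the normalized range the preprocessing emits (roughly [-1, 1]).
    """

    shape: Tuple[int, int, int] = (48, 48, 16)
    bg_sigma: float = 3.0          # smoothing length of the background field
    bg_amp: float = 0.3            # background peak-to-peak scale
    noise_sigma: float = 0.1       # i.i.d. voxel noise
    n_lesions: Tuple[int, int] = (1, 3)
    radius: Tuple[float, float] = (3.0, 6.0)
    delta: float = 0.5             # lesion intensity offset
    theta_max: float = 0.0         # max |rotation| about z, degrees
    t_max: int = 0                 # max |in-plane translation|, voxels

    def __post_init__(self):
        if self.shape[0] % 2:
            raise ValueError("phantom width must be even")
        if self.delta <= 0:
            raise ValueError("lesion offset delta must be positive")
        if self.theta_max < 0 or self.t_max < 0:
            raise ValueError("jitter magnitudes must be >= 0")
        if self.radius[1] >= self.shape[0] // 2:
            raise ValueError("lesion radius exceeds half-width")


@dataclass
class LabeledDataset:
    volumes: np.ndarray        # (N, W, H, D, 1) float32
    labels: np.ndarray         # (N,) int, 0 = bilateral, 1 = unilateral
    masks: np.ndarray          # (N, W, H, D) bool
    manifest: pd.DataFrame     # per-sample label and jitter parameters

    def __post_init__(self):
        if not (len(self.volumes) == len(self.labels) == len(self.masks)
                == len(self.manifest)):
            raise ValueError("dataset fields must have one entry per sample")


def _lesion_blob(shape, center, r, delta):
    """Truncated-Gaussian sphere: peak ``delta`` at ``center``, zero beyond r."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    blob = delta * np.exp(-d2 / (2 * (r / 2.0) ** 2))
    blob[d2 > r * r] = 0.0
    return blob


def _organ_mask(shape):
    w, h, d = shape
    x, y, z = np.ogrid[0:w, 0:h, 0:d]
    return (((x - (w - 1) / 2) / (0.42 * w)) ** 2
            + ((y - (h - 1) / 2) / (0.42 * h)) ** 2
            + ((z - (d - 1) / 2) / (0.46 * d)) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec, label: int,
                     rng: np.random.Generator):
    """One phantom: returns ``(volume (W,H,D,1), mask (W,H,D), info dict)``.

    Pipeline: symmetric background -> lesions (mirrored for label 0) ->
    voxel noise -> rigid jitter.  ``info`` records the jitter actually
    drawn, so downstream analyses can condition on it.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    w, h, d = spec.shape

    field3 = gaussian_filter(rng.standard_normal(spec.shape), spec.bg_sigma)
    sd = field3.std()
    if sd > 0:
        field3 *= spec.bg_amp / (3 * sd)
    v = (field3 + field3[::-1]) / 2.0  # exact mirror symmetry

    n_les = int(rng.integers(spec.n_lesions[0], spec.n_lesions[1] + 1))
    lesions = np.zeros(spec.shape)
    for _ in range(n_les):
        r = float(rng.uniform(*spec.radius))
        ri = int(np.ceil(r))
        # strictly inside one half so a unilateral core never meets its mirror
        cx = int(rng.integers(ri, w // 2 - ri)) if w // 2 - ri > ri else w // 4
        cy = int(rng.integers(ri, h - ri))
        cz = int(rng.integers(min(ri, d // 2), max(d - ri, min(ri, d // 2) + 1)))
        side = int(rng.integers(0, 2))
        if side:
            cx = w - 1 - cx
        lesions += _lesion_blob(spec.shape, (cx, cy, cz), r, spec.delta)
    if label == 0:
        # a + b == b + a exactly in floating point, so this sum is
        # bitwise mirror-symmetric, as is its voxelwise sum with v
        lesions = lesions + lesions[::-1]
    v = v + lesions

    if spec.noise_sigma > 0:
        v = v + spec.noise_sigma * rng.standard_normal(spec.shape)

    mask = _organ_mask(spec.shape)
    theta = float(rng.uniform(-spec.theta_max, spec.theta_max)) \
        if spec.theta_max > 0 else 0.0
    tw = int(rng.integers(-spec.t_max, spec.t_max + 1)) if spec.t_max else 0
    th = int(rng.integers(-spec.t_max, spec.t_max + 1)) if spec.t_max else 0
    if theta != 0.0:
        v = rotate(v, theta, axes=(0, 1), reshape=False, order=1,
                   mode="nearest")
        mask = rotate(mask.astype(np.float32), theta, axes=(0, 1),
                      reshape=False, order=0, mode="nearest") > 0.5
    if tw or th:
        s = ShiftParam(tw, th, 0)
        v = shift3d(v[..., None].astype(np.float32), s)[..., 0]
        mask = shift3d(mask[..., None].astype(np.float32), s)[..., 0] > 0.5

    info = {"label": int(label), "n_lesions": n_les,
            "theta_deg": theta, "t_w": tw, "t_h": th}
    return v[..., None].astype(np.float32), mask, info


def asymmetry_statistic(v: np.ndarray) -> float:
    """Mean absolute LR-mirror residual, ``mean |v - flip_lr(v)|``.

    A model-free asymmetry score: exactly 0 for mirror-symmetric volumes,
    and invariant under flipping the input.
    """
    v = np.asarray(v)
    if v.ndim == 3:
        v = v[..., None]
    if v.shape[0] % 2:
        raise ValueError("width must be even")
    return float(np.abs(v - flip_lr(v)).mean())


def generate_dataset(spec: PhantomSpec, n_per_class: int, seed: int,
                     out_dir: Optional[str] = None) -> LabeledDataset:
    """Balanced, shuffled, fully seeded phantom dataset.

    If ``out_dir`` is given, each sample is written as an NPZ (volume +
    mask) and a ``manifest.csv`` links files to labels and per-sample
    jitter draws.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    vols, masks, rows = [], [], []
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    for i, lab in enumerate(labels):
        v, m, info = generate_phantom(spec, int(lab), rng)
        vols.append(v)
        masks.append(m)
        info["sample"] = i
        rows.append(info)
    order = rng.permutation(len(labels))
    vols = np.stack(vols)[order]
    masks = np.stack(masks)[order]
    labels = labels[order]
    manifest = pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)
    manifest["file"] = [f"phantom_{i:04d}.npz" for i in range(len(labels))]
    ds = LabeledDataset(vols, labels, masks, manifest)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i in range(len(labels)):
            np.savez_compressed(os.path.join(out_dir, manifest["file"][i]),
                                data=vols[i], mask=masks[i], lr_axis=0)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return ds
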
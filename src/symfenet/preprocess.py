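"""Input pipeline: intensity normalization, slice cropping, resampling, I/O.

CT volumes are window-normalized: values are clamped to [-2050, 950] H.U.
and mapped linearly to [-1, 1].  MR volumes are normalized the nnU-Net way:
intensities are clipped to the volume's [0.5, 99.5] percentiles and then
z-scored (a min-max variant to [0, 1] is available).  Axial slices without
organ-mask coverage are dropped, and the volume is resampled to the model's
fixed input grid of 144 x 144 x 48 voxels (left-right, anterior-posterior,
cranio-caudal).  Resampling is trilinear for intensities and nearest for
masks, and deliberately ignores the original voxel spacing: the model
consumes a fixed grid regardless of acquisition geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.transform import resize

__all__ = [
    "CTWindow", "TARGET_SHAPE", "normalize_ct", "normalize_mr_percentile",
    "crop_slices_by_mask", "resample_to", "load_nifti", "load_npz",
    "save_npz", "preprocess_volume",
]

#: Fixed model input grid (W, H, D); W must be even for the LR mirror plane.
TARGET_SHAPE: Tuple[int, int, int] = (144, 144, 48)


@dataclass(frozen=True)
class CTWindow:
    """Linear CT intensity window (Hounsfield units -> normalized range)."""

    lo: float = -2050.0
    hi: float = 950.0
    out_lo: float = -1.0
    out_hi: float = 1.0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("window requires lo < hi")


def _spatial(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if v.ndim == 4:
        return v
    if v.ndim == 3:
        return v[..., None]
    raise ValueError(f"expected rank-3 or rank-4 volume, got shape {v.shape}")


def normalize_ct(v: np.ndarray, window: CTWindow = CTWindow()) -> np.ndarray:
    """Clamp to the CT window and map linearly onto [out_lo, out_hi].

    -2050 H.U. maps to -1.0, 950 H.U. to 1.0, and out-of-window values are
    replaced by the endpoints.  Monotone by construction.
    """
    v = np.asarray(v, dtype=np.float64)
    if np.isnan(v).any():
        raise ValueError("CT volume contains NaN")
    w = window
    clipped = np.clip(v, w.lo, w.hi)
    scale = (w.out_hi - w.out_lo) / (w.hi - w.lo)
    return ((clipped - w.lo) * scale + w.out_lo).astype(np.float32)


def normalize_mr_percentile(v: np.ndarray, lo_pct: float = 0.5,
                            hi_pct: float = 99.5,
                            mode: str = "zscore") -> np.ndarray:
    """Percentile-clip then standardize an MR volume.

    ``mode="zscore"`` (default) clips to the [lo_pct, hi_pct] percentiles
    and z-scores over the clipped volume; ``mode="minmax"`` rescales the
    clipped volume to [0, 1].  A constant volume has no usable contrast and
    is rejected.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty volume")
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    clipped = np.clip(v, lo, hi)
    if mode == "zscore":
        sd = clipped.std()
        if sd == 0:
            raise ValueError("constant volume: zero variance after clipping")
        return ((clipped - clipped.mean()) / sd).astype(np.float32)
    if mode == "minmax":
        if hi == lo:
            raise ValueError("constant volume: degenerate percentile range")
        return ((clipped - lo) / (hi - lo)).astype(np.float32)
    raise ValueError(f"unknown mode {mode!r}")


def crop_slices_by_mask(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep exactly the axial (z) slices where the organ mask has foreground."""
    v4 = _spatial(v)
    m = np.asarray(mask)
    if m.ndim == 4:
        m = m[..., 0]
    if m.shape != v4.shape[:3]:
        raise ValueError(f"mask shape {m.shape} != volume shape {v4.shape[:3]}")
    keep = np.flatnonzero(m.sum(axis=(0, 1)) > 0)
    if keep.size == 0:
        raise ValueError("mask is empty: no axial slice contains the organ")
    out = v4[:, :, keep]
    return out if np.asarray(v).ndim == 4 else out[..., 0]


def resample_to(v: np.ndarray, target: Tuple[int, int, int] = TARGET_SHAPE,
                order: int = 1) -> np.ndarray:
    """Resample spatially to exactly ``target`` voxels.

    ``order=1`` (trilinear) for intensities — linear interpolation cannot
    overshoot the input range — and ``order=0`` (nearest) for masks.
    """
    v4 = _spatial(v)
    if min(v4.shape[:3]) < 1:
        raise ValueError("degenerate input extent")
    out = resize(v4.astype(np.float64), tuple(target) + (v4.shape[3],),
                 order=order, mode="edge", anti_aliasing=False,
                 preserve_range=True).astype(np.float32)
    return out if np.asarray(v).ndim == 4 else out[..., 0]


def load_nifti(path: str) -> np.ndarray:
    """Load a NIfTI volume with the left-right anatomical axis on axis 0.

    The image is reoriented to the closest canonical (RAS) orientation using
    its header codes, so axis 0 runs left-right, axis 1 posterior-anterior,
    axis 2 inferior-superior.  The LR mirror operators only need axis 0 to
    *be* the LR axis; its polarity does not matter to a mirror.
    """
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(path))
    return np.asarray(img.get_fdata(), dtype=np.float32)


def load_npz(path: str) -> Tuple[np.ndarray, int]:
    """Read the NPZ fixture format: keys ``data`` (W,H,D,C) and ``lr_axis``."""
    with np.load(path) as z:
        data = np.asarray(z["data"], dtype=np.float32)
        lr_axis = int(z["lr_axis"]) if "lr_axis" in z else 0
    if lr_axis != 0:
        order = [lr_axis] + [a for a in range(3) if a != lr_axis]
        data = np.transpose(data, order + ([3] if data.ndim == 4 else []))
    return data, 0


def save_npz(path: str, data: np.ndarray, lr_axis: int = 0) -> None:
    np.savez_compressed(path, data=np.asarray(data, dtype=np.float32),
                        lr_axis=np.int64(lr_axis))


def preprocess_volume(v: np.ndarray, task: str = "lung",
                      mask: Optional[np.ndarray] = None,
                      target: Tuple[int, int, int] = TARGET_SHAPE) -> np.ndarray:
    """Full pipeline: normalize (per task), crop by mask if given, resample.

    ``task="lung"`` applies the CT window; ``task="brain"`` the percentile
    normalization.  Always emits exactly ``target`` spatial voxels.
    """
    if task == "lung":
        out = normalize_ct(v)
    elif task == "brain":
        out = normalize_mr_percentile(v)
    else:
        raise ValueError(f"unknown task {task!r}")
    if mask is not None:
        out = crop_slices_by_mask(out, mask)
    return resample_to(out, target)
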
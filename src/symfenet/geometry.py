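"""Deterministic left-right geometry operators.

A volume is a rank-4 ``float`` array of shape ``(W, H, D, C)`` whose first
spatial axis is the body's left-right (LR) axis.  The mid-sagittal mirror
plane sits *between* voxel columns ``W/2 - 1`` and ``W/2``, so the mirror of
voxel ``x`` is voxel ``W - 1 - x`` exactly, with no shared centre voxel and
no interpolation.  ``W`` must therefore be even before any LR fusion; odd
widths are rejected rather than silently cropped, because cropping would
move the mirror plane.

Conventions fixed here and relied on by every other module:

* the *second* half (indices ``[W/2, W)``) is the one that gets flipped and
  shifted; the LR fusion volume lives in the first half's coordinates;
* a positive ``s_w`` moves content toward increasing ``x``
  (``out[x] = in[x - s_w]``), with out-of-range source voxels filled with a
  constant (0 by default — mid-range after CT window normalization);
* ``unfold_output`` concatenates ``[half, flip(half)]`` so indices
  ``[0, W/2)`` carry the half-width features unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "ShiftParam",
    "Volume",
    "LRFusionVolume",
    "mirror_index",
    "split_lr",
    "flip_lr",
    "shift3d",
    "make_lr_fusion",
    "unfold_output",
]


@dataclass(frozen=True)
class ShiftParam:
    """Integer voxel displacement ``(s_w, s_h, s_d)`` applied to the mirrored half.

    Each component is the assumed positional gap between true LR-corresponding
    anatomy along that axis; the zero shift assumes perfect mirror alignment.
    """

    s_w: int = 0
    s_h: int = 0
    s_d: int = 0

    def __post_init__(self):
        for v in (self.s_w, self.s_h, self.s_d):
            if int(v) != v:
                raise ValueError(f"shift components must be integers, got {self}")

    def astuple(self) -> Tuple[int, int, int]:
        return (self.s_w, self.s_h, self.s_d)

    def validate_for(self, shape: Tuple[int, int, int]) -> None:
        """Reject shifts so large that the shifted half is entirely fill."""
        w, h, d = shape
        if abs(self.s_w) >= w // 2 or abs(self.s_h) >= h or abs(self.s_d) >= d:
            raise ValueError(
                f"shift {self.astuple()} out of bounds for half-volume "
                f"({w // 2}, {h}, {d})"
            )


def _check_rank4(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 4:
        raise ValueError(f"expected rank-4 (W,H,D,C) array, got shape {a.shape}")
    return a


@dataclass
class Volume:
    """A rank-4 intensity array ``(W, H, D, C)`` with declared anatomical axes.

    ``axis_roles`` records which array axis carries which body axis; the
    loaders reorient data so that axis 0 is always left-right, axis 1
    anterior-posterior, axis 2 cranio-caudal.
    """

    data: np.ndarray
    axis_roles: Tuple[str, str, str] = ("lr", "ap", "cc")

    def __post_init__(self):
        self.data = _check_rank4(self.data)
        if self.axis_roles[0] != "lr":
            raise ValueError("axis 0 must be the left-right axis; reorient first")
        if min(self.data.shape[:3]) < 2:
            raise ValueError("all spatial extents must be >= 2")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LRFusionVolume:
    """Half-width, channel-doubled volume aligning mirrored voxel pairs.

    Channels ``[0, C)`` are the unchanged first half; channels ``[C, 2C)``
    are the flipped-and-shifted second half, so with the zero shift each
    spatial location holds a voxel and its mirror partner.
    """

    data: np.ndarray
    shift: ShiftParam = field(default_factory=ShiftParam)

    def __post_init__(self):
        self.data = _check_rank4(self.data)
        if self.data.shape[3] % 2:
            raise ValueError("fusion volume must have an even channel count")


def mirror_index(x: int, w: int) -> int:
    """Mirror a 0-based LR index about the mid-sagittal plane: ``W - 1 - x``."""
    if not 0 <= x < w:
        raise IndexError(f"index {x} out of range for extent {w}")
    return w - 1 - x


def split_lr(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split along the LR axis into two equal halves ``[0, W/2)``, ``[W/2, W)``."""
    v = _check_rank4(v)
    w = v.shape[0]
    if w % 2:
        raise ValueError(f"W={w} is odd; pad to even width before LR fusion")
    return v[: w // 2], v[w // 2 :]


def flip_lr(v: np.ndarray) -> np.ndarray:
    """Reverse the LR axis: ``out[x] = in[W-1-x]``.  Involutive."""
    return _check_rank4(v)[::-1]


def shift3d(v: np.ndarray, s: ShiftParam, fill: float = 0.0) -> np.ndarray:
    """Translate by integer voxels with constant fill: ``out[x] = in[x - s_w]`` etc.

    Vacated voxels take ``fill``; the zero shift is the identity.
    """
    v = _check_rank4(v)
    for comp, extent in zip(s.astuple(), v.shape[:3]):
        if abs(comp) >= extent:
            raise ValueError(f"shift {s.astuple()} >= extent of {v.shape[:3]}")
    out = np.full_like(v, fill)
    src = []
    dst = []
    for comp, extent in zip(s.astuple(), v.shape[:3]):
        if comp >= 0:
            src.append(slice(0, extent - comp))
            dst.append(slice(comp, extent))
        else:
            src.append(slice(-comp, extent))
            dst.append(slice(0, extent + comp))
    out[tuple(dst)] = v[tuple(src)]
    return out


def make_lr_fusion(
    v: np.ndarray, s: ShiftParam = ShiftParam(), fill: float = 0.0
) -> LRFusionVolume:
    """Build the LR fusion volume: first half unchanged, second half flipped,
    shifted by ``s`` and stacked on the channel axis.

    With ``s = (0,0,0)``, location ``(x, y, z)`` pairs ``v[x]`` (channels
    ``[0, C)``) with its mirror ``v[W-1-x]`` (channels ``[C, 2C)``).
    """
    v = _check_rank4(v)
    first, second = split_lr(v)
    s.validate_for(v.shape[:3])
    mirrored = shift3d(flip_lr(second), s, fill=fill)
    return LRFusionVolume(np.concatenate([first, mirrored], axis=3), shift=s)


def unfold_output(f_half: np.ndarray) -> np.ndarray:
    """Mirror half-width features back to full width: ``[f, flip(f)]``.

    The result is exactly mirror-symmetric (``out == flip_lr(out)``) and its
    first half equals ``f_half`` unchanged.
    """
    f_half = _check_rank4(f_half)
    return np.concatenate([f_half, flip_lr(f_half)], axis=0)


def unfold_backward(grad: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`unfold_output` for backpropagation."""
    grad = _check_rank4(grad)
    w = grad.shape[0]
    if w % 2:
        raise ValueError("gradient width must be even")
    return grad[: w // 2] + flip_lr(grad[w // 2 :])
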
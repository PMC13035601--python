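"""The symmetric feature extraction (SymFE) block.

One block performs three stages on a volume whose axis 0 is the body's
left-right axis:

1. *LR fusion volume generation* — split at the mid-sagittal plane, flip the
   second half, translate it by the block's integer shift parameter, and
   stack it on the channel axis, so each location of the half-width result
   holds a voxel and its (shifted) mirror partner;
2. *feature extraction* — a 3x3x3 convolution with K kernels over the fused
   channels, optional ReLU, then 3D spatial dropout (train mode only);
3. *output volume generation* — mirror the half-width features back to full
   width, producing an exactly LR-symmetric feature volume.

The block is a hand-differentiated layer: every geometric rearrangement has
its adjoint written out, which the finite-difference tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import Conv3D, Layer, ReLU, SpatialDropout3D
from .geometry import ShiftParam

__all__ = ["SymFEConfig", "SymFEBlock", "symfe_forward", "spatial_dropout3d"]


@dataclass(frozen=True)
class SymFEConfig:
    """Hyper-parameters of one SymFE block.

    ``kernels`` is K, the number of 3D convolution kernels; ``dropout_p`` is
    the spatial-dropout probability (0.1 in the reference training setup);
    ``activation`` is the post-convolution nonlinearity — the block diagram
    shows only convolution and dropout, so ReLU here is an explicit,
    configurable assumption (set ``"none"`` for the literal linear block).
    """

    shift: ShiftParam = field(default_factory=ShiftParam)
    kernels: int = 8
    dropout_p: float = 0.1
    kernel_size: int = 3
    activation: str = "relu"
    bias: bool = True
    fill: float = 0.0

    def __post_init__(self):
        if self.kernels < 1:
            raise ValueError("kernels must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _shift_batched(x: np.ndarray, s: ShiftParam, fill: float) -> np.ndarray:
    """Integer translation of batched (N,W,H,D,C) arrays with constant fill.

    A shift as large as the extent saturates to an all-fill array: inside a
    SymFE block an extreme shift degrades gracefully to "no mirrored
    content" rather than erroring, so large grids remain usable on small
    feature volumes deep in the network.
    """
    out = np.full_like(x, fill)
    for comp, extent in zip(s.astuple(), x.shape[1:4]):
        if abs(comp) >= extent:
            return out
    src, dst = [slice(None)], [slice(None)]
    for comp, extent in zip(s.astuple(), x.shape[1:4]):
        if comp >= 0:
            src.append(slice(0, extent - comp))
            dst.append(slice(comp, extent))
        else:
            src.append(slice(-comp, extent))
            dst.append(slice(0, extent + comp))
    out[tuple(dst)] = x[tuple(src)]
    return out


class SymFEBlock(Layer):
    """Fusion -> conv -> (ReLU) -> spatial dropout -> unfold, batched."""

    def __init__(self, c_in: int, cfg: SymFEConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.c_in = c_in
        self.conv = Conv3D(2 * c_in, cfg.kernels, rng,
                           kernel_size=cfg.kernel_size, bias=cfg.bias)
        self.act = ReLU() if cfg.activation == "relu" else None
        self.drop = SpatialDropout3D(cfg.dropout_p)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train=False, rng=None):
        n, w, h, d, c = x.shape
        if w % 2:
            raise ValueError(f"W={w} is odd; the mid-sagittal split needs even W")
        w2 = w // 2
        first, second = x[:, :w2], x[:, w2:]
        mirrored = _shift_batched(second[:, ::-1], self.cfg.shift, self.cfg.fill)
        fused = np.concatenate([first, mirrored], axis=4)
        f = self.conv.forward(fused, train=train, rng=rng)
        if self.act is not None:
            f = self.act.forward(f, train=train, rng=rng)
        f = self.drop.forward(f, train=train, rng=rng)
        # unfold: [f, flip(f)] along the LR axis -> exactly mirror-symmetric
        return np.concatenate([f, f[:, ::-1]], axis=1)

    def backward(self, grad):
        w = grad.shape[1]
        w2 = w // 2
        g = grad[:, :w2] + grad[:, w2:][:, ::-1]
        g = self.drop.backward(g)
        if self.act is not None:
            g = self.act.backward(g)
        gfused = self.conv.backward(g)
        c = self.c_in
        g_first = gfused[..., :c]
        s = self.cfg.shift
        g_second = _shift_batched(
            gfused[..., c:], ShiftParam(-s.s_w, -s.s_h, -s.s_d), 0.0
        )[:, ::-1]
        return np.concatenate([g_first, g_second], axis=1)


def symfe_forward(v: np.ndarray, block: SymFEBlock, train: bool = False,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run one SymFE block on a single unbatched (W,H,D,C) volume."""
    v = np.asarray(v, dtype=np.float32)
    if v.ndim != 4:
        raise ValueError(f"expected (W,H,D,C) volume, got shape {v.shape}")
    return block.forward(v[None], train=train, rng=rng)[0]


def spatial_dropout3d(f: np.ndarray, p: float, train: bool,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Functional 3D spatial dropout on a single (W,H,D,K) feature volume.

    Eval mode (or p=0) is the identity; in train mode whole channels are
    zeroed with probability ``p`` and survivors scaled by ``1/(1-p)``.
    """
    layer = SpatialDropout3D(p)
    return layer.forward(np.asarray(f)[None], train=train, rng=rng)[0]
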
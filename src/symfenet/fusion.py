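"""Multi-shift symmetric feature extraction (MultiSymFE).

A MultiSymFE module runs a bank of SymFE blocks in parallel, one per integer
shift parameter in a :class:`ShiftGrid`, and fuses their feature volumes by
split attention: each block/channel pair gets a scalar weight
``a_{i,c} = sigmoid(s_{i,c})`` where ``s_{i,c}`` is the global average pool
of that channel, and the fused output is ``O_c = sum_i a_{i,c} F_{i,c}``.

The attention is the *per-entry sigmoid as printed in the model definition*
— it is deliberately not normalized across blocks (a softmax-across-blocks
variant is available behind a flag for comparison, off by default).  The
fusion itself has no learnable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .blocks import SymFEBlock, SymFEConfig
from .engine import Layer
from .geometry import ShiftParam

__all__ = [
    "ShiftGrid",
    "enumerate_shift_grid",
    "grid_by_name",
    "grid_from_yaml",
    "global_avg_pool",
    "attention_weights",
    "split_attention_fuse",
    "MultiSymFE",
    "multisymfe_forward",
]

#: The five shift-grid sizes of the ablation family, by max offset.
GRID_PRESETS = {"33": 8, "25": 6, "17": 4, "9": 2, "1": 0}


@dataclass(frozen=True)
class ShiftGrid:
    """Ordered, duplicate-free set of shift parameters; (0,0,0) always first.

    Ordering is lexicographic by ``(|s_w| + |s_h| + |s_d|, s_w, s_h, s_d)``
    so that checkpoints and attention logs are stable across runs.
    """

    shifts: tuple
    name: str = ""

    def __post_init__(self):
        if len(set(s.astuple() for s in self.shifts)) != len(self.shifts):
            raise ValueError("duplicate shift parameters in grid")
        zero_count = sum(1 for s in self.shifts if s.astuple() == (0, 0, 0))
        if zero_count != 1:
            raise ValueError("grid must contain the zero shift exactly once")

    def __len__(self):
        return len(self.shifts)

    def __iter__(self):
        return iter(self.shifts)


def enumerate_shift_grid(
    max_offset: int,
    step: int = 2,
    include_axis_w: bool = True,
    include_axis_h: bool = True,
    include_diagonals: bool = True,
    include_axis_d: bool = False,
    name: Optional[str] = None,
) -> ShiftGrid:
    """Expand the ``±`` shift-set notation into an explicit grid.

    Produces ``{(0,0,0)} ∪ {(±k,0,0)} ∪ {(0,±k,0)} ∪ {(±k,±k,0)}`` for
    ``k ∈ {step, 2·step, …, max_offset}`` (families switchable), giving
    ``1 + 8·(max_offset/step)`` tuples with all families on — the
    33/25/17/9/1 sequence for max offsets 8/6/4/2/0 at step 2.  Shifts along
    the z axis are off by default (the model targets volumes that are small
    along z) but ``include_axis_d`` adds the ``(0,0,±k)`` family.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_offset < 0 or max_offset % step:
        raise ValueError(f"max_offset {max_offset} must be a multiple of step {step}")
    tuples = {(0, 0, 0)}
    for k in range(step, max_offset + 1, step):
        if include_axis_w:
            tuples.update({(k, 0, 0), (-k, 0, 0)})
        if include_axis_h:
            tuples.update({(0, k, 0), (0, -k, 0)})
        if include_diagonals:
            tuples.update({(sw, sh, 0) for sw in (k, -k) for sh in (k, -k)})
        if include_axis_d:
            tuples.update({(0, 0, k), (0, 0, -k)})
    ordered = sorted(tuples, key=lambda t: (sum(abs(c) for c in t),) + t)
    shifts = tuple(ShiftParam(*t) for t in ordered)
    return ShiftGrid(shifts, name=name if name is not None else str(len(shifts)))


def grid_by_name(name: str) -> ShiftGrid:
    """The named ablation grids: "33", "25", "17", "9", "1"."""
    if name not in GRID_PRESETS:
        raise KeyError(f"unknown grid {name!r}; choose from {sorted(GRID_PRESETS)}")
    return enumerate_shift_grid(GRID_PRESETS[name], step=2, name=name)


def grid_from_yaml(path: str) -> ShiftGrid:
    """Load a grid spec like ``{max_offset: 8, step: 2, axes: [w, h, diag]}``."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    axes = set(cfg.get("axes", ["w", "h", "diag"]))
    return enumerate_shift_grid(
        cfg["max_offset"], step=cfg.get("step", 2),
        include_axis_w="w" in axes, include_axis_h="h" in axes,
        include_diagonals="diag" in axes, include_axis_d="d" in axes)


def global_avg_pool(f: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a single (W,H,D,K) feature volume."""
    f = np.asarray(f)
    if f.ndim != 4 or f.size == 0:
        raise ValueError(f"expected nonempty (W,H,D,K) volume, got shape {f.shape}")
    return f.mean(axis=(0, 1, 2))


def attention_weights(s: np.ndarray) -> np.ndarray:
    """Elementwise logistic sigmoid of the channel-importance matrix."""
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("channel importance must be finite")
    return expit(s)


def split_attention_fuse(features: Sequence[np.ndarray]) -> np.ndarray:
    """Fuse I feature volumes: ``O_c = sum_i sigmoid(mean(F_{i,c})) F_{i,c}``."""
    stack = np.stack([np.asarray(f, dtype=np.float32) for f in features])
    if stack.ndim != 5:
        raise ValueError("each feature must be a rank-4 (W,H,D,K) volume")
    s = stack.mean(axis=(1, 2, 3))              # (I, K)
    a = attention_weights(s).astype(np.float32)  # (I, K)
    return np.einsum("ik,iwhdk->whdk", a, stack)


class _SplitAttentionFuse(Layer):
    """Batched differentiable split attention over I feature volumes.

    Operates on a list of per-block tensors rather than one stacked array
    to keep peak memory at one feature volume per block.
    """

    def __init__(self, normalize_across_blocks: bool = False):
        super().__init__()
        self.softmax_mode = normalize_across_blocks

    def forward(self, feats, train=False, rng=None):
        # feats: list of I arrays (N, W, H, D, K)
        s = np.stack([f.mean(axis=(1, 2, 3)) for f in feats])  # (I, N, K)
        if self.softmax_mode:
            e = np.exp(s - s.max(axis=0, keepdims=True))
            a = e / e.sum(axis=0, keepdims=True)
        else:
            a = expit(s)
        a = a.astype(np.float32)
        self._feats, self._a = feats, a
        out = np.zeros_like(feats[0])
        for ai, f in zip(a, feats):
            out += ai[:, None, None, None, :] * f
        return out

    def backward_block(self, grad, i):
        """Gradient w.r.t. block i's feature volume, given dL/d(output)."""
        f, a = self._feats[i], self._a
        nvox = f.shape[1] * f.shape[2] * f.shape[3]
        da = (grad * f).sum(axis=(1, 2, 3))  # (N, K)
        if self.softmax_mode:
            # cross-block softmax coupling: needs every block's da
            da_all = np.stack([(grad * fi).sum(axis=(1, 2, 3))
                               for fi in self._feats])
            ds = a[i] * (da - (da_all * a).sum(axis=0))
        else:
            ds = da * a[i] * (1.0 - a[i])
        return (a[i][:, None, None, None, :] * grad
                + ds[:, None, None, None, :] / nvox)


class MultiSymFE(Layer):
    """Parallel SymFE blocks over a shift grid, fused by split attention.

    Each grid entry gets its own convolution weights by default (distinct
    blocks in the module diagram); ``share_weights=True`` makes every block
    reuse block 0's kernels, differing only in shift.
    """

    def __init__(self, c_in: int, grid: ShiftGrid, kernels: int,
                 rng: np.random.Generator, dropout_p: float = 0.1,
                 activation: str = "relu", share_weights: bool = False,
                 normalize_across_blocks: bool = False):
        super().__init__()
        self.grid = grid
        self.share_weights = share_weights
        self.blocks: List[SymFEBlock] = []
        for s in grid:
            cfg = SymFEConfig(shift=s, kernels=kernels, dropout_p=dropout_p,
                              activation=activation)
            blk = SymFEBlock(c_in, cfg, rng)
            if share_weights and self.blocks:
                blk.conv.params = self.blocks[0].conv.params
                blk.params = self.blocks[0].params
            self.blocks.append(blk)
        self.fuse = _SplitAttentionFuse(normalize_across_blocks)

    def forward(self, x, train=False, rng=None):
        feats = [b.forward(x, train=train, rng=rng) for b in self.blocks]
        return self.fuse.forward(feats, train=train, rng=rng)

    def backward(self, grad):
        dx = None
        for i, b in enumerate(self.blocks):
            gx = b.backward(self.fuse.backward_block(grad, i))
            dx = gx if dx is None else dx + gx
        return dx

    def named_params(self, prefix=""):
        blocks = self.blocks[:1] if self.share_weights else self.blocks
        for i, b in enumerate(blocks):
            for k, v in b.params.items():
                yield f"{prefix}block{i}.{k}", v

    def named_grads(self, prefix=""):
        if self.share_weights:
            summed = {}
            for b in self.blocks:
                for k, v in b.grads.items():
                    summed[k] = summed.get(k, 0) + v
            for k, v in summed.items():
                yield f"{prefix}block0.{k}", v
        else:
            for i, b in enumerate(self.blocks):
                for k, v in b.grads.items():
                    yield f"{prefix}block{i}.{k}", v

    def attention_table(self, v: np.ndarray) -> pd.DataFrame:
        """Eval-mode attention weights for one (W,H,D,C) volume.

        Rows are block shifts, columns are channels — useful for inspecting
        which shift variants the fusion favours on a given input.
        """
        feats = np.stack([b.forward(v[None].astype(np.float32)) for b in self.blocks])
        a = attention_weights(feats.mean(axis=(1, 2, 3, 4)))
        idx = [str(b.cfg.shift.astuple()) for b in self.blocks]
        return pd.DataFrame(a, index=idx,
                            columns=[f"c{c}" for c in range(a.shape[1])])


def multisymfe_forward(v: np.ndarray, module: MultiSymFE, train: bool = False,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run a MultiSymFE module on a single unbatched (W,H,D,C) volume."""
    v = np.asarray(v, dtype=np.float32)
    if v.ndim != 4:
        raise ValueError(f"expected (W,H,D,C) volume, got shape {v.shape}")
    return module.forward(v[None], train=train, rng=rng)[0]
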
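"""The LR relationship-aware volume classifier.

The classifier stacks MultiSymFE modules with growing kernel counts K and
max pooling between stages, then classifies with global average pooling and
a dense two-class head.  The original description fixes the module but not
the macro-architecture (stage count, K schedule, downsampling, head), so
those are explicit, configurable assumptions here; the default is three
stages with doubling widths.  Pooling factors are validated so the volume
width stays even at every stage — the mid-sagittal mirror plane must keep
falling between voxel columns.

A shift-matched plain-CNN control (`build_control_cnn`) with the same stage
widths but ordinary full-width convolutions is provided as the baseline for
the synthetic benchmark.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

from .engine import (BatchNorm, Conv3D, Dense, GlobalAvgPool, MaxPool3D,
                     ReLU, SpatialDropout3D, softmax)
from .fusion import MultiSymFE, grid_by_name

__all__ = ["ModelConfig", "Prediction", "SymFENet", "build_model",
           "model_config_from_yaml", "build_control_cnn", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``stages`` lists ``(K, pool)`` pairs: kernel count of the stage's
    MultiSymFE module and the max-pool factor applied after it.  ``grid`` is
    the shift-grid name shared by all stages ("33", "25", "17", "9", "1").
    """

    stages: Tuple[Tuple[int, int], ...] = ((16, 2), (32, 2), (64, 2))
    grid: str = "33"
    dropout_p: float = 0.1
    activation: str = "relu"
    batch_norm: bool = True
    head_hidden: int = 0
    n_classes: int = 2
    in_channels: int = 1
    share_weights: bool = False
    normalize_across_blocks: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.stages:
            raise ValueError("need at least one stage")
        grid_by_name(self.grid)  # validates the name

    def validate_input_shape(self, shape: Tuple[int, int, int]) -> None:
        w, h, d = shape
        for k, pool in self.stages:
            if w % 2:
                raise ValueError(
                    f"width {w} becomes odd inside the model; the LR mirror "
                    f"plane would no longer fall between voxels")
            if w % pool or h % pool or d % pool:
                raise ValueError(f"stage pool {pool} does not divide ({w},{h},{d})")
            w, h, d = w // pool, h // pool, d // pool
        if w % 2:
            raise ValueError("width after final pooling must stay even")


@dataclass
class Prediction:
    probs: np.ndarray   # length-n_classes, sums to 1
    label: int
    logits: np.ndarray


class _Sequential:
    """Ordered layers with flat, name-addressed parameters."""

    def __init__(self, named_layers):
        self.named_layers = list(named_layers)

    def forward(self, x, train=False, rng=None):
        for _, layer in self.named_layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for _, layer in reversed(self.named_layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = {}
        for name, layer in self.named_layers:
            if isinstance(layer, MultiSymFE):
                out.update(dict(layer.named_params(prefix=f"{name}.")))
            else:
                out.update({f"{name}.{k}": v for k, v in layer.params.items()})
        return out

    def grads(self):
        out = {}
        for name, layer in self.named_layers:
            if isinstance(layer, MultiSymFE):
                out.update(dict(layer.named_grads(prefix=f"{name}.")))
            else:
                out.update({f"{name}.{k}": v for k, v in layer.grads.items()})
        return out


class SymFENet(_Sequential):
    """MultiSymFE stages -> global average pool -> dense two-class head."""

    def __init__(self, cfg: ModelConfig, control: bool = False):
        self.cfg = cfg
        self.control = control
        rng = np.random.default_rng(cfg.seed)
        grid = grid_by_name(cfg.grid)
        layers = []
        c = cfg.in_channels
        for j, (k, pool) in enumerate(cfg.stages):
            if control:
                layers.append((f"stage{j}.conv", Conv3D(c, k, rng)))
                layers.append((f"stage{j}.relu", ReLU()))
                layers.append((f"stage{j}.drop", SpatialDropout3D(cfg.dropout_p)))
            else:
                layers.append((f"stage{j}.msfe", MultiSymFE(
                    c, grid, k, rng, dropout_p=cfg.dropout_p,
                    activation=cfg.activation, share_weights=cfg.share_weights,
                    normalize_across_blocks=cfg.normalize_across_blocks)))
            if cfg.batch_norm:
                # stage-boundary normalization: the fused feature volumes
                # carry a large common-mode component that otherwise drowns
                # the class signal in minibatch gradients
                layers.append((f"stage{j}.bn", BatchNorm(k)))
            layers.append((f"stage{j}.pool", MaxPool3D(pool)))
            c = k
        layers.append(("head.gap", GlobalAvgPool()))
        if cfg.batch_norm:
            layers.append(("head.bn", BatchNorm(c)))
        if cfg.head_hidden:
            layers.append(("head.fc0", Dense(c, cfg.head_hidden, rng)))
            layers.append(("head.relu", ReLU()))
            c = cfg.head_hidden
        head = Dense(c, cfg.n_classes, rng)
        # start at the chance predictor: logits 0 regardless of feature
        # scale, so early training is not spent undoing a large random head
        head.params["W"][...] = 0.0
        layers.append(("head.fc", head))
        super().__init__(layers)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected batched (N,W,H,D,C), got {x.shape}")
        self.cfg.validate_input_shape(x.shape[1:4])
        return super().forward(x, train=train, rng=rng)

    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params().values())

    def state_arrays(self):
        """Trainable parameters plus batch-norm running statistics."""
        out = dict(self.params())
        for name, layer in self.named_layers:
            if isinstance(layer, BatchNorm):
                out[f"{name}.running_mean"] = layer.running_mean
                out[f"{name}.running_var"] = layer.running_var
        return out


def model_config_from_yaml(path: str) -> ModelConfig:
    """Load a ModelConfig from YAML; ``stages`` as a list of [K, pool]."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "stages" in raw:
        raw["stages"] = tuple(tuple(s) for s in raw["stages"])
    return ModelConfig(**raw)


def build_model(cfg: ModelConfig) -> SymFENet:
    """Deterministically initialized LR-aware classifier for ``cfg.seed``."""
    return SymFENet(cfg)


def build_control_cnn(cfg: ModelConfig) -> SymFENet:
    """Plain-CNN control: same stage widths and pooling, no fusion/attention."""
    return SymFENet(cfg, control=True)


def predict(model: SymFENet, v: np.ndarray) -> Prediction:
    """Eval-mode class probabilities for one (W,H,D,C) volume."""
    v = np.asarray(v, dtype=np.float32)
    if v.ndim == 3:
        v = v[..., None]
    logits = model.forward(v[None])[0]
    probs = softmax(logits)
    return Prediction(probs=probs, label=int(np.argmax(probs)), logits=logits)


def save_checkpoint(model: SymFENet, directory: str) -> None:
    """Write weights (NPZ) plus a self-describing architecture JSON."""
    os.makedirs(directory, exist_ok=True)
    cfg = asdict(model.cfg)
    cfg["stages"] = [list(s) for s in model.cfg.stages]
    cfg["control"] = model.control
    with open(os.path.join(directory, "architecture.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
    np.savez(os.path.join(directory, "weights.npz"), **model.state_arrays())


def load_checkpoint(directory: str) -> SymFENet:
    with open(os.path.join(directory, "architecture.json")) as fh:
        cfg = json.load(fh)
    control = cfg.pop("control", False)
    cfg["stages"] = tuple(tuple(s) for s in cfg["stages"])
    model = SymFENet(ModelConfig(**cfg), control=control)
    with np.load(os.path.join(directory, "weights.npz")) as npz:
        state = model.state_arrays()
        for k in state:
            state[k][...] = npz[k]
    return model
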
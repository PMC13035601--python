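"""Training loop, LR schedule, cross-validation and classification metrics.

The optimization recipe follows the reference setup: Adam, minibatch 8,
linear learning-rate warmup to a peak of 0.005 over the first 10 epochs,
then cosine decay to zero over the remaining epochs; spatial dropout 0.1;
stratified four-fold cross-validation with accuracy, F1, precision and
recall reported per fold and as mean +/- sample SD.  Everything is seeded
and single-threaded-deterministic: the same seed reproduces the same report
bit for bit.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .engine import Adam, softmax, softmax_cross_entropy
from .net import ModelConfig, SymFENet, build_control_cnn, build_model
from .synthetic import LabeledDataset

__all__ = ["TrainConfig", "MetricsReport", "train_config_from_yaml",
           "lr_at", "kfold_split",
           "compute_metrics", "aggregate_reports", "train_model",
           "evaluate_model", "run_experiment", "two_sided_ttest"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (defaults = the lung-task recipe)."""

    epochs: int = 80
    batch_size: int = 8
    peak_lr: float = 0.005
    warmup_epochs: int = 10
    folds: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup_epochs must be <= epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class MetricsReport:
    """Binary classification metrics, each a fraction in [0, 1].

    ``degenerate`` flags metrics whose defining ratio had a zero
    denominator (reported as 0 by convention).
    """

    accuracy: float
    f1: float
    precision: float
    recall: float
    degenerate: Tuple[str, ...] = ()

    def as_percent(self) -> Dict[str, float]:
        return {m: 100.0 * getattr(self, m)
                for m in ("accuracy", "f1", "precision", "recall")}


def train_config_from_yaml(path: str) -> TrainConfig:
    """Load a TrainConfig from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return TrainConfig(**raw)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for ``epoch`` (0-based): linear warmup, cosine decay.

    Warmup rises linearly so the *last* warmup epoch runs exactly at the
    peak; the cosine then decays from the peak to ~0 at the final epoch.
    Continuous at the junction and nonincreasing afterwards.
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.peak_lr * (epoch + 1) / cfg.warmup_epochs
    span = cfg.epochs - cfg.warmup_epochs
    if span == 0:
        return cfg.peak_lr
    t = (epoch - cfg.warmup_epochs) / span
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * t))


def kfold_split(labels: Sequence[int], k: int = 4,
                seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold: disjoint, exhaustive, label-balanced test sets."""
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"need at least k={k} samples, got {len(labels)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    positive_label: int = 1) -> MetricsReport:
    """Accuracy, F1, precision, recall from the binary confusion matrix.

    Zero-denominator ratios (e.g. precision with no positive predictions)
    are reported as 0 and flagged in ``degenerate``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    tp = int(np.sum((y_true == positive_label) & (y_pred == positive_label)))
    fp = int(np.sum((y_true != positive_label) & (y_pred == positive_label)))
    fn = int(np.sum((y_true == positive_label) & (y_pred != positive_label)))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = float(np.mean(y_true == y_pred))
    return MetricsReport(accuracy, f1, precision, recall, tuple(degenerate))


def aggregate_reports(reports: Sequence[MetricsReport]) -> Dict[str, Dict[str, float]]:
    """Mean and sample SD (ddof=1) of each metric across folds."""
    out = {"mean": {}, "sd": {}}
    for m in ("accuracy", "f1", "precision", "recall"):
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        out["mean"][m] = float(vals.mean())
        out["sd"][m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


def train_model(model: SymFENet, x: np.ndarray, y: np.ndarray,
                cfg: TrainConfig, verbose: bool = False) -> Dict[str, list]:
    """Minibatch Adam training with the warmup+cosine schedule.

    Returns a history of per-epoch mean loss and learning rate.  Aborts
    with a diagnostic if the loss diverges to NaN.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y)
    opt = Adam(model.params(), lr=lr_at(0, cfg))
    history = {"loss": [], "lr": []}
    n = len(x)
    for epoch in range(cfg.epochs):
        opt.lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: loss={loss} at epoch {epoch}, "
                    f"lr={opt.lr:.4g}")
            model.backward(dlogits)
            opt.step(model.grads())
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} "
                  f"lr={opt.lr:.5f} loss={history['loss'][-1]:.4f}",
                  file=sys.stderr)
    return history


def evaluate_model(model: SymFENet, x: np.ndarray,
                   batch_size: int = 8) -> np.ndarray:
    """Eval-mode predicted labels for a batch of volumes."""
    preds = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(np.ascontiguousarray(
            x[start:start + batch_size], dtype=np.float32))
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def run_experiment(model_cfg: ModelConfig, train_cfg: TrainConfig,
                   dataset: LabeledDataset, control: bool = False,
                   verbose: bool = False) -> Dict:
    """Stratified k-fold cross-validation, one model trained per fold.

    Returns per-fold metric reports, their mean +/- sample SD, and the
    training histories.  Fully reproducible under fixed seeds.
    """
    x, y = dataset.volumes, dataset.labels
    folds = kfold_split(y, k=train_cfg.folds, seed=train_cfg.seed)
    reports, histories = [], []
    for fold, (tr, te) in enumerate(folds):
        fold_cfg = replace(model_cfg, seed=model_cfg.seed + 1000 * fold)
        model = build_control_cnn(fold_cfg) if control else build_model(fold_cfg)
        fold_train = replace(train_cfg, seed=train_cfg.seed + 1000 * fold)
        hist = train_model(model, x[tr], y[tr], fold_train, verbose=verbose)
        y_pred = evaluate_model(model, x[te], batch_size=train_cfg.batch_size)
        reports.append(compute_metrics(y[te], y_pred))
        histories.append(hist)
        if verbose:
            print(f"fold {fold}: acc={reports[-1].accuracy:.3f}",
                  file=sys.stderr)
    return {"folds": reports, **aggregate_reports(reports),
            "histories": histories}


def two_sided_ttest(a: Sequence[float], b: Sequence[float],
                    paired: bool = False) -> Tuple[float, float]:
    """Two-sided t-test between two sets of fold metrics: ``(t, p)``."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    res = stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)
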
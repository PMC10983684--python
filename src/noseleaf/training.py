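"""Cross-entropy / SGD training with a step learning-rate schedule,
plus stratified K-fold splitting.

The loss is the multiclass cross-entropy  L = −Σ_k y_k log f_k(x)  (natural
log), computed internally from log-probabilities for numerical stability.
The optimizer is plain stochastic gradient descent,
θ_{t+1} = θ_t − α·∇L, with optional momentum (off by default).  The
learning rate starts at 0.01 and is multiplied by 0.75 every 20 epochs:

    lr(epoch) = lr0 · decay_factor ^ floor(epoch / decay_period)

Training is seeded and single-threaded-deterministic: the same seed gives
identical loss trajectories and final weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .manifest import DatasetManifest

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "cross_entropy", "lr_at_epoch", "sgd_step", "SGD",
    "train", "kfold_split", "TrainResult",
]


@dataclass
class TrainConfig:
    """Training hyperparameters.  ``lr0``/``decay_factor``/``decay_period``
    follow the published schedule; batch size, epoch budget and momentum
    were not reported and default to 32 / 100 / 0."""

    lr0: float = 0.01
    decay_factor: float = 0.75
    decay_period: int = 20
    epochs: int = 100
    batch_size: int = 32
    momentum: float = 0.0
    seed: int = 0
    stop_at_train_accuracy: float | None = None

    def __post_init__(self):
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError("decay_factor must be in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")


def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  eps: float = 1e-12) -> float:
    """−Σ_k y_k log f_k(x), natural log; mean over the batch when given
    2-D inputs.  Zero true-class probabilities are clamped at ``eps`` and
    flagged in the log rather than raised."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    onehot = np.atleast_2d(np.asarray(onehot, dtype=np.float64))
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {onehot.shape}")
    if not np.all((onehot == 0) | (onehot == 1)) or not np.all(onehot.sum(1) == 1):
        raise ValueError("labels must be one-hot")
    p_true = (probs * onehot).sum(axis=1)
    if np.any(p_true <= 0):
        logger.warning("true-class probability <= 0 clamped at eps=%g", eps)
    return float(-np.log(np.clip(p_true, eps, None)).mean())


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_period)


def sgd_step(theta: np.ndarray, gradient: np.ndarray, lr: float) -> np.ndarray:
    """One plain SGD update θ − α·g as a pure function."""
    theta = np.asarray(theta, dtype=np.float64)
    gradient = np.asarray(gradient, dtype=np.float64)
    if theta.shape != gradient.shape:
        raise ValueError("gradient length must match parameter length")
    if not np.isfinite(gradient).all():
        raise FloatingPointError("non-finite gradient")
    return theta - lr * gradient


class SGD:
    """In-place SGD over a module's parameters, optional momentum."""

    def __init__(self, params: list[nn.Parameter], momentum: float = 0.0):
        self.params = params
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params] if momentum else None

    def step(self, lr: float) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if not np.isfinite(p.grad).all():
                raise FloatingPointError("non-finite gradient during training")
            if self._velocity is not None:
                v = self._velocity[i]
                v *= self.momentum
                v += p.grad
                p.data -= lr * v
            else:
                p.data -= lr * p.grad


@dataclass
class TrainResult:
    log: pd.DataFrame            # epoch, lr, train_loss, train_accuracy, eval_accuracy
    best_state: dict             # checkpoint of the best monitored accuracy
    best_epoch: int
    best_accuracy: float


def _accuracy_eval(model, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    preds = model.predict_proba(x, batch_size=batch_size).argmax(axis=1)
    return float((preds == y).mean())


def train(model, train_data: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig,
          eval_data: tuple[np.ndarray, np.ndarray] | None = None) -> TrainResult:
    """Seeded mini-batch SGD training.

    ``train_data`` is (images (N,3,H,W) float32, integer labels).  Per-epoch
    training loss/accuracy come from the training-time forward passes; when
    ``eval_data`` is given the model is additionally scored on it each epoch
    and the best-scoring weights are retained.  Training stops early once
    ``cfg.stop_at_train_accuracy`` is reached, if set.
    """
    x, y = train_data
    if len(x) == 0:
        raise ValueError("empty training split")
    num_classes = model.config.num_classes
    if y.min() < 0 or y.max() >= num_classes:
        raise ValueError("label outside the model's class range")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), momentum=cfg.momentum)
    onehot = np.eye(num_classes, dtype=np.float32)[y]

    rows = []
    best_state, best_epoch, best_acc = model.state_dict(), -1, -np.inf
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        model.train(True)
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x[idx], onehot[idx]
            logits = model.forward(nn.Tensor(xb))
            logp = nn.log_softmax(logits)
            loss = (logp * nn.Tensor(yb)).sum() * (-1.0 / len(idx))
            model.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(1) == y[idx]).sum())
        train_loss = float(np.mean(losses))
        train_acc = correct / len(x)
        eval_acc = (np.nan if eval_data is None else
                    _accuracy_eval(model, *eval_data, cfg.batch_size))
        monitored = train_acc if eval_data is None else eval_acc
        if monitored > best_acc:
            best_acc, best_epoch, best_state = monitored, epoch, model.state_dict()
        rows.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                     "train_accuracy": train_acc, "eval_accuracy": eval_acc})
        logger.info("epoch %d lr %.5f loss %.4f train_acc %.3f eval_acc %s",
                    epoch, lr, train_loss, train_acc,
                    f"{eval_acc:.3f}" if eval_data is not None else "-")
        if (cfg.stop_at_train_accuracy is not None
                and train_acc >= cfg.stop_at_train_accuracy):
            break
    return TrainResult(pd.DataFrame(rows), best_state, best_epoch, best_acc)


def kfold_split(manifest: DatasetManifest, k: int,
                seed: int = 0) -> list[tuple[DatasetManifest, DatasetManifest]]:
    """Stratified K-fold partition of a manifest.

    Folds are pairwise disjoint, cover every record, and per-class fold
    sizes differ by at most one.  Every class must have at least ``k``
    records.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = manifest.records
    counts = manifest.per_class_counts()
    small = counts[counts < k]
    if len(small):
        raise ValueError(f"classes smaller than k={k}: {list(small.index)}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(df), dtype=int)
    for cls in manifest.class_names:
        idx = np.flatnonzero((df["label"] == cls).to_numpy())
        idx = rng.permutation(idx)
        for f in range(k):
            fold_of[idx[f::k]] = f
    out = []
    for f in range(k):
        val = df[fold_of == f].copy()
        trn = df[fold_of != f].copy()
        out.append((DatasetManifest(trn, class_names=list(manifest.class_names)),
                    DatasetManifest(val, class_names=list(manifest.class_names))))
    return out
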
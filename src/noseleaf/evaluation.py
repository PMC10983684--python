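"""Multiclass evaluation surface: confusion matrix, accuracy, per-class
precision/recall/F1, macro-F1, one-vs-rest ROC/AUC, and report artifacts.

Definitions follow the standard one-vs-rest reduction of a K-class
confusion matrix (rows = true label, columns = predicted label):

    accuracy  = trace / total
    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1        = 2·P·R / (P + R)       macro-F1 = unweighted mean of F1

Degenerate 0/0 ratios are reported as 0 with a flag rather than raised.
Percentages destined for tables are rounded half-up to two decimals.
ROC curves and AUC use scikit-learn's trapezoidal implementation; the
multiclass default aggregation is micro-average one-vs-rest, with macro
and per-class modes available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix", "ClassMetrics", "RocCurve", "EvaluationReport",
    "confusion_matrix", "accuracy", "precision_recall_f1", "macro_f1",
    "roc_auc", "evaluate", "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed percent tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                # (K, K) int, rows true, cols predicted
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_names:
            self.class_names = [str(i) for i in range(len(self.counts))]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class ClassMetrics:
    class_name: str
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False          # flags a 0/0 precision or recall


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    label: str = ""


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float
    per_class: list[ClassMetrics]
    macro_f1: float
    roc: dict[str, RocCurve]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": [{
                "class": m.class_name, "tp": m.tp, "fp": m.fp, "tn": m.tn,
                "fn": m.fn, "precision": m.precision, "recall": m.recall,
                "f1": m.f1, "degenerate": m.degenerate} for m in self.per_class],
            "auc": {k: v.auc for k, v in self.roc.items()},
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
            "provenance": self.provenance,
        }


def confusion_matrix(true_labels, predicted_labels, num_classes: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.bincount(t * num_classes + p,
                         minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes),
                           class_names or [])


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_recall_f1(cm: ConfusionMatrix, class_index: int) -> ClassMetrics:
    k = class_index
    if not 0 <= k < len(cm.counts):
        raise ValueError(f"class index {k} out of range")
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return ClassMetrics(cm.class_names[k], tp, fp, tn, fn,
                        precision, recall, f1, degenerate)


def macro_f1(per_class: list[ClassMetrics]) -> float:
    if not per_class:
        raise ValueError("need at least one class")
    return float(np.mean([m.f1 for m in per_class]))


def roc_auc(scores: np.ndarray, true_labels, mode: str = "micro",
            class_names: list[str] | None = None) -> dict[str, RocCurve]:
    """One-vs-rest ROC analysis of per-sample probability vectors.

    ``mode``: "per_class" (one curve per class), "micro" (pooled one-vs-rest
    decisions, the default), or "macro" (mean of per-class AUCs, curve by
    interpolation on a common FPR grid).  Classes absent from the truth are
    skipped with a warning entry rather than raised.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if scores.ndim != 2 or len(scores) != len(y):
        raise ValueError("scores must be (n_samples, n_classes) aligned with labels")
    k = scores.shape[1]
    names = class_names or [str(i) for i in range(k)]
    onehot = np.eye(k)[y]

    def curve(truth, score, label):
        fpr, tpr, thr = _sk_roc_curve(truth, score)
        return RocCurve(thr, fpr, tpr, float(_sk_auc(fpr, tpr)), label)

    per_class: dict[str, RocCurve] = {}
    for i in range(k):
        if onehot[:, i].sum() == 0:
            import logging
            logging.getLogger(__name__).warning(
                "class %s absent from truth; skipped in ROC", names[i])
            continue
        per_class[names[i]] = curve(onehot[:, i], scores[:, i], names[i])

    if mode == "per_class":
        return per_class
    if mode == "micro":
        return {"micro": curve(onehot.ravel(), scores.ravel(), "micro")}
    if mode == "macro":
        grid = np.linspace(0.0, 1.0, 101)
        mean_tpr = np.mean(
            [np.interp(grid, c.fpr, c.tpr) for c in per_class.values()], axis=0)
        mean_tpr[0] = 0.0
        macro_auc = float(np.mean([c.auc for c in per_class.values()]))
        return {"macro": RocCurve(np.array([]), grid, mean_tpr, macro_auc, "macro")}
    raise ValueError(f"unknown mode '{mode}'")


def evaluate(model, images: np.ndarray, labels: np.ndarray,
             class_names: list[str] | None = None,
             out_dir: str | Path | None = None,
             batch_size: int = 16,
             provenance: dict | None = None) -> EvaluationReport:
    """Run inference on a test set and assemble the full report.

    Argmax ties break toward the lowest class index.  When ``out_dir`` is
    given, writes ``confusion.csv``, ``metrics.json``, one
    ``roc_<class>.csv`` per class and a ROC plot.
    """
    if len(images) == 0:
        raise ValueError("empty test set")
    k = model.config.num_classes
    names = class_names or [str(i) for i in range(k)]
    if len(names) != k:
        raise ValueError(f"model expects {k} classes, got {len(names)} names")
    scores = model.predict_proba(images, batch_size=batch_size)
    preds = scores.argmax(axis=1)     # np.argmax: first (lowest) index wins ties
    cm = confusion_matrix(labels, preds, k, names)
    per_class = [precision_recall_f1(cm, i) for i in range(k)]
    roc_all = roc_auc(scores, labels, mode="per_class", class_names=names)
    roc_all.update(roc_auc(scores, labels, mode="micro", class_names=names))
    report = EvaluationReport(cm, accuracy(cm), per_class,
                              macro_f1(per_class), roc_all,
                              provenance or {})
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: EvaluationReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.confusion.to_frame().to_csv(out_dir / "confusion.csv")
    (out_dir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    for name, c in report.roc.items():
        pd.DataFrame({"threshold": np.resize(c.thresholds, len(c.fpr)),
                      "fpr": c.fpr, "tpr": c.tpr}).to_csv(
            out_dir / f"roc_{name}.csv", index=False)
    _plot_roc(report.roc, out_dir / "roc.png")


def _plot_roc(curves: dict[str, RocCurve], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=f"{name} (AUC={c.auc:.3f})", lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_training_curves(log: pd.DataFrame, path: str | Path) -> None:
    """Loss and accuracy curves from a per-epoch training log."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(log["epoch"], log["train_loss"], label="train loss")
    ax1.set_xlabel("epoch"); ax1.set_ylabel("cross-entropy"); ax1.legend()
    ax2.plot(log["epoch"], log["train_accuracy"], label="train accuracy")
    if log["eval_accuracy"].notna().any():
        ax2.plot(log["epoch"], log["eval_accuracy"], label="eval accuracy")
    ax2.set_xlabel("epoch"); ax2.set_ylabel("accuracy"); ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
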
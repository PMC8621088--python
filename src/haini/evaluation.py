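"""Per-class and averaged classification metrics plus one-vs-rest ROC/AUC.

Every class is scored one-vs-rest from its TP/FP/TN/FN counts:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)

A zero denominator yields 0 and sets a per-class warning flag rather
than raising.  Macro averages are unweighted means over the classes
present in ``y_true``; micro averages pool the counts (for single-label
multiclass data micro precision = micro recall = overall accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import DimensionError


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class, in catalog order."""

    classes: tuple
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_samples: int

    def for_class(self, cls) -> dict[str, int]:
        i = self.classes.index(cls)
        return {"tp": int(self.tp[i]), "fp": int(self.fp[i]),
                "tn": int(self.tn[i]), "fn": int(self.fn[i])}


@dataclass
class MetricsReport:
    """Per-class and averaged metrics; ``per_class`` rows mirror the
    (class, recall, precision, F1) report table."""

    classes: tuple
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    zero_division_flags: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    macro_auc: float | None = None

    def per_class_table(self) -> pd.DataFrame:
        rows = {
            "class": list(self.classes),
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "support": self.support.astype(int),
        }
        if self.auc:
            rows["auc"] = [self.auc.get(c) for c in self.classes]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1},
            "micro": {"precision": self.micro_precision, "recall": self.micro_recall,
                      "f1": self.micro_f1},
            "per_class": {
                str(c): {"precision": float(self.precision[i]),
                         "recall": float(self.recall[i]),
                         "f1": float(self.f1[i]),
                         "support": int(self.support[i])}
                for i, c in enumerate(self.classes)
            },
            "zero_division_flags": {str(k): v for k, v in self.zero_division_flags.items()},
        }
        if self.auc:
            d["auc"] = {str(c): (None if v is None else float(v))
                        for c, v in self.auc.items()}
            d["macro_auc"] = self.macro_auc
        return d

    def write(self, json_path=None, csv_path=None) -> None:
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_dict(), indent=2))
        if csv_path is not None:
            self.per_class_table().to_csv(csv_path, index=False)


def confusion(y_true, y_pred, classes=None) -> ConfusionCounts:
    """One-vs-rest confusion counts per class.

    ``classes`` defaults to the sorted union of observed labels; for
    every class TP+FP+TN+FN equals the total sample count.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise DimensionError(
            f"y_true and y_pred lengths differ: {y_true.shape} vs {y_pred.shape}")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = tuple(classes)
    n = len(y_true)
    tp = np.zeros(len(classes), dtype=int)
    fp = np.zeros(len(classes), dtype=int)
    fn = np.zeros(len(classes), dtype=int)
    for i, c in enumerate(classes):
        t = y_true == c
        p = y_pred == c
        tp[i] = int(np.sum(t & p))
        fp[i] = int(np.sum(~t & p))
        fn[i] = int(np.sum(t & ~p))
    tn = n - tp - fp - fn
    return ConfusionCounts(classes, tp, fp, tn, fn, n)


def _safe_div(num, den, flags, kind, classes):
    out = np.zeros(len(num), dtype=float)
    for i in range(len(num)):
        if den[i] == 0:
            flags.setdefault(classes[i], []).append(kind)
        else:
            out[i] = num[i] / den[i]
    return out


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate precision/recall/F1/accuracy from one-vs-rest counts."""
    classes = counts.classes
    flags: dict = {}
    precision = _safe_div(counts.tp, counts.tp + counts.fp, flags, "precision", classes)
    recall = _safe_div(counts.tp, counts.tp + counts.fn, flags, "recall", classes)
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    support = counts.tp + counts.fn
    n = counts.n_samples
    accuracy = float(counts.tp.sum() / n) if n else 0.0

    present = support > 0  # macro averages over classes present in y_true
    if present.any():
        macro_p = float(precision[present].mean())
        macro_r = float(recall[present].mean())
        macro_f = float(f1[present].mean())
    else:
        macro_p = macro_r = macro_f = 0.0

    tp_sum, fp_sum, fn_sum = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    micro_p = float(tp_sum / (tp_sum + fp_sum)) if tp_sum + fp_sum else 0.0
    micro_r = float(tp_sum / (tp_sum + fn_sum)) if tp_sum + fn_sum else 0.0
    micro_f = (2 * micro_p * micro_r / (micro_p + micro_r)
               if micro_p + micro_r else 0.0)

    return MetricsReport(classes, precision, recall, f1, support, accuracy,
                         macro_p, macro_r, macro_f, micro_p, micro_r,
                         float(micro_f), flags)


def roc_auc_ovr(y_true, scores, classes) -> tuple[dict, float | None]:
    """One-vs-rest trapezoidal AUC per class plus the macro average.

    ``scores`` columns must follow ``classes`` order.  A class absent
    from ``y_true`` has no positives to rank and is reported as None.
    """
    y_true = np.asarray(y_true)
    scores = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    classes = tuple(classes)
    if scores.shape != (len(y_true), len(classes)):
        raise DimensionError(
            f"score matrix shape {scores.shape} does not match "
            f"{len(y_true)} samples x {len(classes)} classes")
    aucs: dict = {}
    for j, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            aucs[c] = None
            continue
        aucs[c] = float(roc_auc_score(pos.astype(int), scores[:, j]))
    defined = [v for v in aucs.values() if v is not None]
    macro = float(np.mean(defined)) if defined else None
    return aucs, macro


def evaluate(y_true, y_pred, scores=None, classes=None) -> MetricsReport:
    """Full report: counts -> metrics, optionally plus ROC/AUC."""
    counts = confusion(y_true, y_pred, classes)
    report = metrics_from_counts(counts)
    if scores is not None:
        report.auc, report.macro_auc = roc_auc_ovr(y_true, scores, counts.classes)
    return report
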
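"""Decision fusion and multiclass evaluation.

The ensemble prediction for each window is the plurality label of the
three pipeline predictions; when all three disagree the third
(convolutional) pipeline's label is returned, which makes fusion
deterministic and argument-order dependent only in the no-majority
case.

Evaluation follows the standard multiclass conventions: an l x l
confusion matrix C with rows = actual and columns = predicted; per
class i, precision P_i = TP_i / (TP_i + FP_i), recall
R_i = TP_i / (TP_i + FN_i) and F1_i their harmonic mean, with
zero-denominator cases defined as 0; macro averages are unweighted
per-class means (macro F1 defaults to the mean of per-class F1, with
the harmonic-of-macro-P/R variant available under a flag), weighted
averages are support-weighted means, and micro averages pool TP/FP/FN
over classes (for single-label multiclass, micro precision = micro
recall = accuracy).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .activities import ACTIVITY_CLASSES, ACTIVITY_NAMES

logger = logging.getLogger(__name__)


def majority_vote(l1, l2, l3):
    """Plurality of three labels; three-way ties go to the third
    (convolutional) pipeline."""
    counts = Counter([l1, l2, l3])
    label, count = counts.most_common(1)[0]
    if count >= 2:
        return label
    return l3


def fuse_predictions(l1: np.ndarray, l2: np.ndarray, l3: np.ndarray) -> np.ndarray:
    if not (len(l1) == len(l2) == len(l3)):
        raise ValueError("prediction vectors must share a length")
    return np.array(
        [majority_vote(a, b, c) for a, b, c in zip(l1, l2, l3)], dtype=object
    )


@dataclass
class PredictionSet:
    """Pooled out-of-fold predictions: truth, the three pipelines and
    the fused label, plus the subject each window came from."""

    true: np.ndarray
    fe: np.ndarray
    lda: np.ndarray
    cnn: np.ndarray
    fused: np.ndarray
    subject_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "true": self.true,
                "fe": self.fe,
                "lda": self.lda,
                "cnn": self.cnn,
                "fused": self.fused,
            }
        )


def confusion(true, pred, class_order=ACTIVITY_CLASSES) -> np.ndarray:
    """l x l confusion matrix, rows = actual, columns = predicted."""
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(true) != len(pred):
        raise ValueError("true/pred length mismatch")
    if len(true) == 0:
        raise ValueError("cannot build a confusion matrix from no predictions")
    known = set(class_order)
    stray = (set(true) | set(pred)) - known
    if stray:
        raise ValueError(f"labels outside class order: {sorted(map(str, stray))}")
    return _sk_confusion(true.astype(str), pred.astype(str), labels=[str(c) for c in class_order])


def per_class_metrics(c: np.ndarray, class_order=ACTIVITY_CLASSES) -> pd.DataFrame:
    """Per-class TP/FP/FN, precision, recall, F1 and support from a
    confusion matrix; zero-denominator metrics are defined as 0."""
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    support = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
    if np.any((tp + fp) == 0) or np.any((tp + fn) == 0):
        logger.warning("class with zero predicted or actual count; metric defined as 0")
    pr = precision + recall
    f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return pd.DataFrame(
        {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        },
        index=list(class_order)[: c.shape[0]],
    )


def averaged_metrics(
    per_class: pd.DataFrame,
    mode: str,
    macro_f1: str = "mean",
) -> tuple[float, float, float]:
    """(P, R, F1) under macro, micro or weighted averaging.

    ``macro_f1="mean"`` averages per-class F1 (the convention of
    standard classification reports); ``"harmonic"`` returns the
    harmonic mean of macro precision and macro recall instead.
    """
    if per_class["support"].sum() == 0:
        raise ValueError("zero total support")
    if mode == "macro":
        p = float(per_class["precision"].mean())
        r = float(per_class["recall"].mean())
        if macro_f1 == "mean":
            f1 = float(per_class["f1"].mean())
        elif macro_f1 == "harmonic":
            f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        else:
            raise ValueError("macro_f1 must be 'mean' or 'harmonic'")
        return p, r, f1
    if mode == "weighted":
        w = per_class["support"].to_numpy(dtype=float)
        w = w / w.sum()
        p = float((per_class["precision"] * w).sum())
        r = float((per_class["recall"] * w).sum())
        f1 = float((per_class["f1"] * w).sum())
        return p, r, f1
    if mode == "micro":
        tp = per_class["tp"].sum()
        fp = per_class["fp"].sum()
        fn = per_class["fn"].sum()
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return float(p), float(r), float(f1)
    raise ValueError(f"unknown averaging mode: {mode}")


def class_weights(labels) -> dict:
    """Inverse-frequency weights: w_i = K_total / (l_present * K_i), so
    the rarest class always receives the largest weight."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("no labels")
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    total = counts.sum()
    return {c: total / (len(classes) * k) for c, k in zip(classes, counts)}


@dataclass
class ClassificationReport:
    """Confusion matrix plus per-class and averaged metrics."""

    confusion_matrix: np.ndarray
    per_class: pd.DataFrame
    class_order: tuple
    macro_f1_convention: str = "mean"

    @classmethod
    def from_predictions(
        cls, true, pred, class_order=ACTIVITY_CLASSES, macro_f1: str = "mean"
    ) -> "ClassificationReport":
        cm = confusion(true, pred, class_order)
        return cls(cm, per_class_metrics(cm, class_order), tuple(class_order), macro_f1)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion_matrix) / self.confusion_matrix.sum())

    @property
    def macro_avg(self):
        return averaged_metrics(self.per_class, "macro", self.macro_f1_convention)

    @property
    def micro_avg(self):
        return averaged_metrics(self.per_class, "micro")

    @property
    def weighted_avg(self):
        return averaged_metrics(self.per_class, "weighted")

    def to_text(self) -> str:
        """Pretty per-class table with 2-decimal half-up rounding."""

        def r2(v):
            return Decimal(repr(float(v))).quantize(Decimal("0.01"), ROUND_HALF_UP)

        lines = [f"{'class':>16} {'precision':>9} {'recall':>7} {'f1':>6} {'support':>8}"]
        for cls_label, row in self.per_class.iterrows():
            name = ACTIVITY_NAMES.get(cls_label, str(cls_label))
            lines.append(
                f"{name:>16} {r2(row.precision):>9} {r2(row.recall):>7}"
                f" {r2(row.f1):>6} {int(row.support):>8}"
            )
        total = int(self.per_class["support"].sum())
        for label, (p, rr, f1) in (
            ("macro avg", self.macro_avg),
            ("weighted avg", self.weighted_avg),
        ):
            lines.append(f"{label:>16} {r2(p):>9} {r2(rr):>7} {r2(f1):>6} {total:>8}")
        lines.append(f"{'accuracy':>16} {r2(self.accuracy):>9}")
        return "\n".join(lines)
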
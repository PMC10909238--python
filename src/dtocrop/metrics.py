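"""Confusion matrices, one-vs-rest per-class metrics and macro averages.

Per-class metrics binarize each class against the rest of the confusion
matrix: for class k with counts TP, FP, FN, TN,

    accuracy  = (TP + TN) / N
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-score   = 2 P R / (P + R)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

reported in percent (MCC in [-100, 100]).  Ratios with a zero denominator are
reported as 0 and flagged rather than raised, so degenerate classifier
candidates inside an optimizer loop still receive finite fitness.  Averages
are unweighted (macro) arithmetic means over classes; display rounding is
half-up to two decimals with raw values retained.  The optimizer fitness is
the classification error rate, misclassified / total * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractViolation

__all__ = [
    "confusion_matrix",
    "per_class_metrics",
    "macro_average",
    "micro_average",
    "error_rate_fitness",
    "round_half_up",
    "EvaluationReport",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f_score", "mcc")


def round_half_up(x, ndigits: int = 2):
    """Decimal half-up rounding (98.125 -> 98.13), elementwise on arrays/Series."""
    q = Decimal(10) ** -ndigits

    def _one(v: float) -> float:
        return float(Decimal(repr(float(v))).quantize(q, rounding=ROUND_HALF_UP))

    if isinstance(x, pd.Series):
        return x.map(_one)
    if isinstance(x, (np.ndarray, list, tuple)):
        return np.vectorize(_one)(np.asarray(x, dtype=float))
    return _one(x)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """C x C count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ContractViolation("y_true and y_pred must be equal-length 1-D vectors")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ContractViolation(
                f"{name}[{bad[0]}] = {arr[bad[0]]} outside [0, {n_classes - 1}]"
            )
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_ratio(num: float, den: float, flags: list[str], label: str) -> float:
    if den == 0:
        flags.append(label)
        return 0.0
    return num / den


def per_class_metrics(confusion: np.ndarray) -> pd.DataFrame:
    """One-vs-rest metric table in percent, one row per class.

    The returned frame has columns ``accuracy, precision, recall, f_score,
    mcc`` plus ``flags``: a semicolon-joined list of metrics whose denominator
    was zero (reported as 0).
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ContractViolation("confusion matrix must be square and non-empty")
    if np.any(cm < 0):
        raise ContractViolation("confusion matrix entries must be non-negative")
    N = cm.sum()
    rows = []
    for k in range(cm.shape[0]):
        tp = float(cm[k, k])
        fn = float(cm[k].sum() - tp)
        fp = float(cm[:, k].sum() - tp)
        tn = float(N - tp - fn - fp)
        flags: list[str] = []
        acc = _safe_ratio(tp + tn, N, flags, "accuracy")
        prec = _safe_ratio(tp, tp + fp, flags, "precision")
        rec = _safe_ratio(tp, tp + fn, flags, "recall")
        f1 = _safe_ratio(2 * prec * rec, prec + rec, flags, "f_score")
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_ratio(tp * tn - fp * fn, denom, flags, "mcc")
        rows.append(
            {
                "accuracy": 100 * acc,
                "precision": 100 * prec,
                "recall": 100 * rec,
                "f_score": 100 * f1,
                "mcc": 100 * mcc,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def macro_average(per_class: pd.DataFrame, ndigits: int | None = 2) -> pd.Series:
    """Unweighted arithmetic mean of each metric column over classes.

    ``ndigits`` applies display rounding (half-up); pass ``None`` for the raw
    means.
    """
    if len(per_class) < 1:
        raise ContractViolation("per-class table must have at least one row")
    cols = [c for c in METRIC_COLUMNS if c in per_class.columns]
    means = per_class[cols].mean(axis=0)
    return round_half_up(means, ndigits) if ndigits is not None else means


def micro_average(confusion: np.ndarray, ndigits: int | None = 2) -> pd.Series:
    """Pooled (micro) metrics.

    For single-label multiclass data the pooled one-vs-rest TP equals the
    confusion-matrix trace and pooled FP = pooled FN, so micro precision,
    recall, F-score and accuracy all collapse to trace / N.
    """
    cm = np.asarray(confusion)
    N = cm.sum()
    acc = float(np.trace(cm) / N) if N else 0.0
    out = pd.Series({m: 100 * acc for m in ("accuracy", "precision", "recall", "f_score")})
    return round_half_up(out, ndigits) if ndigits is not None else out


def error_rate_fitness(y_true, y_pred) -> float:
    """Classifier error rate in percent: misclassified / total * 100.

    This is the fitness both tuning stages minimize; it always equals
    100 minus the micro accuracy.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ContractViolation("empty input")
    if y_true.shape != y_pred.shape:
        raise ContractViolation("y_true and y_pred must have equal length")
    return float(np.mean(y_true != y_pred) * 100.0)


@dataclass
class EvaluationReport:
    """Confusion matrix plus per-class and macro-averaged metrics for one split."""

    confusion: np.ndarray
    per_class: pd.DataFrame
    averages: pd.Series
    split_tag: str = ""
    class_names: list[str] = field(default_factory=list)

    @classmethod
    def from_predictions(
        cls,
        y_true,
        y_pred,
        class_names: list[str],
        split_tag: str = "",
    ) -> "EvaluationReport":
        cm = confusion_matrix(y_true, y_pred, len(class_names))
        per_class = per_class_metrics(cm)
        per_class.insert(0, "class", class_names)
        return cls(
            confusion=cm,
            per_class=per_class,
            averages=macro_average(per_class, ndigits=None),
            split_tag=split_tag,
            class_names=list(class_names),
        )

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows plus an Average row, metrics display-rounded."""
        body = self.per_class.copy()
        for c in METRIC_COLUMNS:
            body[c] = round_half_up(body[c], 2)
        avg = {"class": "Average", **round_half_up(self.averages, 2).to_dict(), "flags": ""}
        return pd.concat([body, pd.DataFrame([avg])], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def confusion_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.confusion, index=self.class_names, columns=self.class_names
        ).to_csv(path)

    def to_dict(self) -> dict:
        return {
            "split_tag": self.split_tag,
            "n_samples": self.n_samples,
            "confusion": self.confusion.tolist(),
            "class_names": self.class_names,
            "per_class": self.per_class.drop(columns=["class"], errors="ignore").to_dict(
                orient="list"
            ),
            "averages": {k: float(v) for k, v in self.averages.items()},
        }
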
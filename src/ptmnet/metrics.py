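"""Confusion-table accuracy measures, ROC curves, AUC and MCC.

Conventions: classification error E = (FP + FN) / n; recall R (equal to
sensitivity and TPR) = TP / (TP + FN); precision P = TP / (TP + FP);
FPR = FP / (FP + TN).  A rate with a zero denominator is *undefined* and
reported as NaN with its name recorded in ``EvalResult.undefined`` —
never silently coerced to 0, which would corrupt checkpoint selection.

The ROC sweeps thresholds over the distinct scores (score >= t predicts
positive) plus sentinels, so the curve always starts at (0, 0) and ends
at (1, 1).  AUC is computed as the Mann-Whitney rank probability that a
random positive outscores a random negative (ties count 1/2), which
equals the trapezoidal area under that ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass
class EvalResult:
    """Confusion counts, derived rates, ROC points and AUC for one model/split."""

    tp: int
    fp: int
    tn: int
    fn: int
    error: float
    recall: float
    precision: float
    tpr: float
    fpr: float
    specificity: float
    accuracy: float
    mcc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = math.nan
    undefined: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "error": self.error,
            "recall": self.recall,
            "precision": self.precision,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def _check_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values, int)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return arr


def confusion(decisions: Sequence[int], labels: Sequence[int]) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts; they partition the sample count."""
    d = _check_binary(decisions, "decisions")
    y = _check_binary(labels, "labels")
    if d.size != y.size:
        raise ValueError(f"length mismatch: {d.size} decisions vs {y.size} labels")
    tp = int(((d == 1) & (y == 1)).sum())
    fp = int(((d == 1) & (y == 0)).sum())
    tn = int(((d == 0) & (y == 0)).sum())
    fn = int(((d == 0) & (y == 1)).sum())
    return tp, fp, tn, fn


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def rates(tp: int, fp: int, tn: int, fn: int) -> dict:
    """All derived accuracy measures from a confusion table.

    Returns a dict with keys error, recall, precision, tpr, fpr,
    specificity, accuracy, mcc and ``undefined`` (the set of measures
    whose denominator was zero, reported as NaN).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n < 1:
        raise ValueError("empty confusion table")
    undefined: set[str] = set()
    recall = _ratio(tp, tp + fn, "recall", undefined)
    if math.isnan(recall):
        undefined.add("tpr")
    precision = _ratio(tp, tp + fp, "precision", undefined)
    fpr = _ratio(fp, fp + tn, "fpr", undefined)
    specificity = _ratio(tn, tn + fp, "specificity", undefined)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        undefined.add("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / denom
    return {
        "error": (fp + fn) / n,
        "recall": recall,
        "precision": precision,
        "tpr": recall,
        "fpr": fpr,
        "specificity": specificity,
        "accuracy": (tp + tn) / n,
        "mcc": mcc,
        "undefined": frozenset(undefined),
    }


def _check_scored(scores: Sequence[float], labels: Sequence[int]):
    s = np.asarray(scores, float)
    y = _check_binary(labels, "labels")
    if s.size != y.size:
        raise ValueError(f"length mismatch: {s.size} scores vs {y.size} labels")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("ROC/AUC require both classes present")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float]]:
    """(FPR, TPR) points swept over the distinct score thresholds.

    A sample is predicted positive when its score >= threshold; a +inf
    sentinel contributes (0, 0) and the smallest score gives (1, 1).
    """
    s, y = _check_scored(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    points = [(0.0, 0.0)]
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tpr = float((pred & (y == 1)).sum()) / n_pos
        fpr = float((pred & (y == 0)).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    # Deduplicate while preserving the sweep order (FPR is non-decreasing).
    dedup = [points[0]]
    for p in points[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return dedup


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-probability AUC (Mann-Whitney, ties counted half).

    Equals the trapezoidal area under :func:`roc_curve` and the
    probability that a random positive is ranked above a random
    negative.
    """
    s, y = _check_scored(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def trapezoid_auc(roc: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a list of (FPR, TPR) points."""
    pts = np.asarray(roc, float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate(
    scores: Sequence[float],
    decisions: Sequence[int],
    labels: Sequence[int],
    with_roc: bool = True,
) -> EvalResult:
    """Full evaluation of scored binary predictions against labels."""
    tp, fp, tn, fn = confusion(decisions, labels)
    r = rates(tp, fp, tn, fn)
    y = np.asarray(labels, int)
    both = bool(y.any() and not y.all())
    roc = roc_curve(scores, labels) if (with_roc and both) else []
    a = auc(scores, labels) if both else math.nan
    undef = set(r["undefined"])
    if not both:
        undef.add("auc")
    return EvalResult(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        error=r["error"],
        recall=r["recall"],
        precision=r["precision"],
        tpr=r["tpr"],
        fpr=r["fpr"],
        specificity=r["specificity"],
        accuracy=r["accuracy"],
        mcc=r["mcc"],
        roc=roc,
        auc=a,
        undefined=frozenset(undef),
    )
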
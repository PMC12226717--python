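"""Metrics, curves and the stratified cross-validation harness.

Binary metrics follow the usual confusion-count definitions
(accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP)); a zero denominator yields NaN ("undefined"), never 0.
For the four-class task a single sensitivity/specificity is produced
by macro (unweighted one-vs-rest) averaging, and multiclass AUC is the
unweighted mean of one-vs-rest AUCs.  The positive class of the binary
pre-diagnosis task is "serious" (the disease-worse class).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "CurveResult",
    "CVReport",
    "confusion_metrics",
    "multiclass_metrics",
    "roc_auc",
    "multiclass_auc",
    "calibration_curve",
    "decision_curve",
    "kfold_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, pred: Sequence[int], truth: Sequence[int]) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=int)
        truth = np.asarray(truth, dtype=int)
        if pred.shape != truth.shape:
            raise ValueError("pred/truth misaligned")
        return cls(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            tn=int(((pred == 0) & (truth == 0)).sum()),
            fp=int(((pred == 1) & (truth == 0)).sum()),
            fn=int(((pred == 0) & (truth == 1)).sum()),
        )


@dataclass
class CurveResult:
    """Points of an ROC / calibration / net-benefit curve."""

    kind: str  # "roc" | "calibration" | "net_benefit"
    x: np.ndarray
    y: np.ndarray
    auc: Optional[float] = None
    reference: Optional[dict] = None
    extras: dict = field(default_factory=dict)


@dataclass
class CVReport:
    per_fold: list[dict]
    mean: dict
    sd: dict
    best_fold_id: int
    best_fold_metrics: dict


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity and specificity from confusion counts."""
    if counts.n == 0:
        raise ValueError("all confusion counts are zero")
    return {
        "accuracy": (counts.tp + counts.tn) / counts.n,
        "sensitivity": _safe_div(counts.tp, counts.tp + counts.fn),
        "specificity": _safe_div(counts.tn, counts.tn + counts.fp),
    }


def multiclass_metrics(pred: Sequence[int], truth: Sequence[int],
                       n_classes: int = 4) -> dict:
    """Exact-match accuracy, macro one-vs-rest sensitivity/specificity,
    and the n_classes x n_classes confusion matrix (rows=truth)."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred/truth must be aligned and nonempty")
    if ((pred < 0) | (pred >= n_classes) | (truth < 0) | (truth >= n_classes)).any():
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = skm.confusion_matrix(truth, pred, labels=list(range(n_classes)))
    sens, spec = [], []
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        sens.append(_safe_div(tp, tp + fn))
        spec.append(_safe_div(tn, tn + fp))
    return {
        "accuracy": float((pred == truth).mean()),
        "macro_sensitivity": float(np.nanmean(sens)),
        "macro_specificity": float(np.nanmean(spec)),
        "confusion_matrix": cm,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> CurveResult:
    """ROC curve and trapezoidal AUC (rank / Mann-Whitney tie convention)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresh = skm.roc_curve(labels, scores)
    auc = float(skm.roc_auc_score(labels, scores))
    return CurveResult(kind="roc", x=fpr, y=tpr, auc=auc,
                       extras={"thresholds": thresh})


def multiclass_auc(proba: np.ndarray, truth: Sequence[int]) -> float:
    """Macro (unweighted mean) one-vs-rest AUC for the 4-class task."""
    proba = np.asarray(proba, dtype=float)
    truth = np.asarray(truth, dtype=int)
    aucs = []
    for c in range(proba.shape[1]):
        y = (truth == c).astype(int)
        if len(np.unique(y)) < 2:
            continue
        aucs.append(skm.roc_auc_score(y, proba[:, c]))
    if not aucs:
        raise ValueError("no class with both positive and negative samples")
    return float(np.mean(aucs))


def calibration_curve(scores: Sequence[float], labels: Sequence[int],
                      n_bins: int = 10) -> CurveResult:
    """Reliability curve on equal-width bins over [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    xs, ys, counts = [], [], []
    for b in range(n_bins):
        mask = idx == b
        counts.append(int(mask.sum()))
        if mask.any():
            xs.append(float(scores[mask].mean()))
            ys.append(float(labels[mask].mean()))
    return CurveResult(kind="calibration", x=np.asarray(xs), y=np.asarray(ys),
                       extras={"bin_counts": counts})


def decision_curve(scores: Sequence[float], labels: Sequence[int],
                   thresholds: Sequence[float] | None = None) -> CurveResult:
    """Net benefit NB(t) = TP(t)/n - FP(t)/n * t/(1-t) over a threshold grid.

    Includes the "treat none" (identically 0) and "treat all"
    (pi - (1-pi) t/(1-t)) reference curves.  Grid endpoints at exactly
    0 or 1 are excluded (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    bad = (thresholds <= 0) | (thresholds >= 1)
    if bad.any():
        warnings.warn("thresholds at 0 or 1 excluded from decision curve",
                      RuntimeWarning, stacklevel=2)
        thresholds = thresholds[~bad]
    n = len(labels)
    pi = labels.mean()
    nb, nb_all = [], []
    for t in thresholds:
        pred = scores >= t
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        w = t / (1.0 - t)
        nb.append(tp / n - fp / n * w)
        nb_all.append(pi - (1.0 - pi) * w)
    return CurveResult(
        kind="net_benefit", x=thresholds, y=np.asarray(nb),
        reference={"treat_none": np.zeros_like(thresholds),
                   "treat_all": np.asarray(nb_all)},
        extras={"prevalence": float(pi)},
    )


def kfold_cv(ds, k: int = 5, trainer: Callable = None, evaluator: Callable = None,
             seed: int = 0, select_by: str = "accuracy") -> CVReport:
    """Stratified k-fold cross-validation over a Dataset.

    ``trainer(train_ds)`` returns a fitted model; ``evaluator(model,
    test_ds)`` returns a flat dict of float metrics.  The best fold is
    selected by ``select_by`` (accuracy, matching the convention of
    reporting both fold means and the best cross-validated model).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ds) < k:
        raise ValueError("need at least k samples")
    try:
        y = ds.labels("glaucoma")
    except ValueError:
        y = ds.labels("stage")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(ds)), y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        model = trainer(ds.subset(tr))
        m = evaluator(model, ds.subset(te))
        per_fold.append({"fold": fold, **m})
    keys = [k_ for k_ in per_fold[0] if k_ != "fold"]
    mean = {k_: float(np.mean([f[k_] for f in per_fold])) for k_ in keys}
    sd = {k_: float(np.std([f[k_] for f in per_fold], ddof=1)) for k_ in keys}
    best = max(per_fold, key=lambda f: f[select_by])
    return CVReport(per_fold=per_fold, mean=mean, sd=sd,
                    best_fold_id=best["fold"],
                    best_fold_metrics={k_: best[k_] for k_ in keys})
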
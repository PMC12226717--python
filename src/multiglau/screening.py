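"""Tier-1 tabular glaucoma screening.

A scikit-learn-style classifier over the five cheap clinical features
(age, gender, BCVA, IOP, CDR) with four selectable model families
(KNN, SVM, logistic regression, XGBoost), Bayesian (expected-
improvement) hyperparameter search with cross-validated AUC as the
objective, operating-point selection at a target sensitivity or
specificity, and exact Shapley-value attribution.

SVM probabilities come from Platt-style calibration (the libsvm
``probability=True`` path).  Class imbalance is unweighted by default;
pass ``class_weight="balanced"`` to reweight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from scipy.stats import norm

from .core.types import FEATURE_ORDER, ClinicalRecord, Dataset

__all__ = [
    "ScreeningClassifier",
    "OperatingPoint",
    "ShapReport",
    "train_screening",
    "predict_proba",
    "select_operating_point",
    "explain_shap",
]


# ---------------------------------------------------------------------------
# hyperparameter search spaces (unit-box parameterisation)
# ---------------------------------------------------------------------------
# Each dim: (name, kind, low, high); kind "log" | "int" | "float" | "intlog"

_SPACES = {
    "xgb": [("max_depth", "int", 2, 8),
            ("learning_rate", "log", 0.01, 0.5),
            ("n_estimators", "int", 50, 400)],
    "lr": [("C", "log", 1e-3, 100.0)],
    "svm": [("C", "log", 1e-2, 100.0),
            ("gamma", "log", 1e-3, 10.0)],
    "knn": [("n_neighbors", "int", 3, 50),
            ("weights", "int", 0, 1)],  # 0=uniform, 1=distance
}


def _decode(kind: str, u: np.ndarray) -> dict:
    hp = {}
    for (name, t, lo, hi), ui in zip(_SPACES[kind], u):
        if t == "log":
            hp[name] = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        elif t == "int":
            hp[name] = int(round(lo + ui * (hi - lo)))
        else:
            hp[name] = float(lo + ui * (hi - lo))
    if kind == "knn":
        hp["weights"] = "distance" if hp["weights"] == 1 else "uniform"
    return hp


def _make_estimator(kind: str, hp: dict, seed: int, class_weight=None):
    if kind == "xgb":
        import xgboost as xgb
        return xgb.XGBClassifier(
            max_depth=hp.get("max_depth", 4),
            learning_rate=hp.get("learning_rate", 0.1),
            n_estimators=hp.get("n_estimators", 200),
            subsample=0.9, colsample_bytree=0.9,
            eval_metric="logloss", random_state=seed, n_jobs=1,
            scale_pos_weight=1.0,
        )
    if kind == "lr":
        base = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000,
                                  class_weight=class_weight, random_state=seed)
    elif kind == "svm":
        # Platt-style sigmoid calibration provides the probabilistic scores
        base = CalibratedClassifierCV(
            SVC(C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
                kernel="rbf", class_weight=class_weight, random_state=seed),
            method="sigmoid", ensemble=False, cv=3)
    elif kind == "knn":
        base = KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 15),
                                    weights=hp.get("weights", "uniform"))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", base)])


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


class ScreeningClassifier(BaseEstimator, ClassifierMixin):
    """Tabular screening classifier with built-in Bayesian hyperparameter search.

    Parameters
    ----------
    kind : {"xgb", "lr", "svm", "knn"}
        Model family.
    hpo_budget : int
        Total number of hyperparameter evaluations (random warm-up plus
        GP-guided expected-improvement proposals).  ``0`` skips tuning
        and fits the documented defaults.
    n_folds : int
        Stratified folds for the cross-validated-AUC objective.
    seed : int
        Drives fold shuffling, the search and the final refit.

    Attributes
    ----------
    estimator_ : fitted inner model (pipeline for knn/svm/lr).
    best_params_ : tuned hyperparameters.
    cv_auc_ : mean cross-validated AUC of the winning configuration.
    """

    def __init__(self, kind: str = "xgb", hpo_budget: int = 50, n_folds: int = 5,
                 seed: int = 0, class_weight=None):
        self.kind = kind
        self.hpo_budget = hpo_budget
        self.n_folds = n_folds
        self.seed = seed
        self.class_weight = class_weight

    # -- internal ------------------------------------------------------
    def _cv_auc(self, X, y, hp) -> float:
        n_folds = min(self.n_folds, int(np.bincount(y).min()))
        if n_folds < 2:
            raise ValueError("need at least 2 samples of each class for CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=self.seed)
        aucs = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            est = _make_estimator(self.kind, hp, self.seed, self.class_weight)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], est.predict_proba(X[te])[:, 1]))
        return float(np.mean(aucs)) if aucs else 0.5

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_ORDER):
            raise ValueError(f"X must be n x {len(FEATURE_ORDER)} "
                             f"({', '.join(FEATURE_ORDER)})")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if self.hpo_budget < 0:
            raise ValueError("hpo_budget must be >= 0")

        if self.kind not in _SPACES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        dims = len(_SPACES[self.kind])
        rng = np.random.default_rng(self.seed)
        trials_u, trials_auc = [], []
        if self.hpo_budget > 0:
            n_init = min(self.hpo_budget, max(5, 2 * dims))
            for i in range(self.hpo_budget):
                if i < n_init:
                    u = rng.random(dims)
                else:
                    gp = GaussianProcessRegressor(
                        kernel=Matern(nu=2.5, length_scale=0.3),
                        alpha=1e-6, normalize_y=True,
                        random_state=self.seed)
                    gp.fit(np.array(trials_u), np.array(trials_auc))
                    cand = rng.random((256, dims))
                    mu, sd = gp.predict(cand, return_std=True)
                    u = cand[int(np.argmax(_expected_improvement(mu, sd, max(trials_auc))))]
                trials_u.append(u)
                trials_auc.append(self._cv_auc(X, y, _decode(self.kind, u)))
            best_u = trials_u[int(np.argmax(trials_auc))]
            self.best_params_ = _decode(self.kind, best_u)
            self.cv_auc_ = float(max(trials_auc))
        else:
            self.best_params_ = {}
            self.cv_auc_ = self._cv_auc(X, y, {})

        self.estimator_ = _make_estimator(self.kind, self.best_params_,
                                          self.seed, self.class_weight)
        self.estimator_.fit(X, y)
        self.classes_ = classes
        self.feature_order_ = list(FEATURE_ORDER)
        self.X_train_ = X
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_ORDER):
            raise ValueError(f"X must be n x {len(FEATURE_ORDER)}")
        nan_cols = np.isnan(X).any(axis=0)
        if nan_cols.any():
            missing = [FEATURE_ORDER[j] for j in np.flatnonzero(nan_cols)]
            raise ValueError(f"missing feature value(s) in {missing}; impute first")
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def decision_margin(self, X):
        """Raw margin (log-odds for xgb, logit of probability otherwise)."""
        p = self.predict_proba(X)[:, 1]
        if self.kind == "xgb":
            import xgboost as xgb
            return self.estimator_.get_booster().predict(
                xgb.DMatrix(np.asarray(X, dtype=float)), output_margin=True)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


# ---------------------------------------------------------------------------
# operating points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    achieved_sensitivity: float
    achieved_specificity: float
    mode: str  # "target_sensitivity" | "target_specificity"
    saturated: bool = False


def _sens_spec_at(scores, labels, t):
    pred = scores >= t
    pos = labels == 1
    sens = float(pred[pos].mean()) if pos.any() else math.nan
    spec = float((~pred[~pos]).mean()) if (~pos).any() else math.nan
    return sens, spec


def select_operating_point(scores: Sequence[float], labels: Sequence[int],
                           target: float, mode: str) -> OperatingPoint:
    """Pick the score threshold achieving a target sensitivity or specificity.

    The candidate grid is exhaustive: the midpoints of consecutive
    sorted unique scores plus one threshold below the minimum and one
    above the maximum.  ``mode="target_sensitivity"`` keeps thresholds
    with sensitivity >= target and picks the one maximizing specificity
    (ties broken towards the higher threshold); symmetric for
    ``"target_specificity"``.  An unattainable target returns the
    extreme threshold with ``saturated=True``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels misaligned")
    if not 0.0 < target <= 1.0:
        raise ValueError("target must be in (0, 1]")
    if mode not in ("target_sensitivity", "target_specificity"):
        raise ValueError(f"unknown mode {mode!r}")

    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]])
    rows = [(t, *_sens_spec_at(scores, labels, t)) for t in candidates]
    if mode == "target_sensitivity":
        feasible = [r for r in rows if r[1] >= target - 1e-12]
        if feasible:
            best = max(feasible, key=lambda r: (r[2], r[0]))
            return OperatingPoint(best[0], best[1], best[2], mode, False)
        t, s, p = rows[0]  # lowest threshold: predict everything positive
        return OperatingPoint(t, s, p, mode, True)
    feasible = [r for r in rows if r[2] >= target - 1e-12]
    if feasible:
        best = max(feasible, key=lambda r: (r[1], -r[0]))
        return OperatingPoint(best[0], best[1], best[2], mode, False)
    t, s, p = rows[-1]  # highest threshold: predict everything negative
    return OperatingPoint(t, s, p, mode, True)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

@dataclass
class ShapReport:
    per_sample: np.ndarray      # n x 5 attributions
    base_value: float
    ranking: list[str]          # feature names by mean |attribution|
    output_space: str           # "margin" (xgb) | "probability"

    def additivity_residual(self, outputs: np.ndarray) -> np.ndarray:
        """outputs - (base + row sums); zero under the efficiency axiom."""
        return np.asarray(outputs) - (self.base_value + self.per_sample.sum(axis=1))


def _exact_interventional_shap(predict_fn, X, background) -> tuple[np.ndarray, float]:
    """Exact Shapley values over all subsets of the 5 features.

    v(S) is the mean model output with the features in S taken from the
    explained sample and the rest from each background row.
    """
    n, d = X.shape
    nb = background.shape[0]
    subsets = []
    for size in range(d + 1):
        subsets.extend(combinations(range(d), size))
    sub_index = {s: i for i, s in enumerate(subsets)}
    # batch evaluation: for each subset, overlay x_S on every background row
    v = np.zeros((len(subsets), n))
    for si, S in enumerate(subsets):
        block = np.repeat(background[None, :, :], n, axis=0)  # n x nb x d
        for j in S:
            block[:, :, j] = X[:, j][:, None]
        out = predict_fn(block.reshape(n * nb, d)).reshape(n, nb)
        v[si] = out.mean(axis=1)
    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros((n, d))
    for j in range(d):
        for S in subsets:
            if j in S:
                continue
            w = fact[len(S)] * fact[d - len(S) - 1] / fact[d]
            phi[:, j] += w * (v[sub_index[tuple(sorted(S + (j,)))]] - v[sub_index[S]])
    base = float(v[sub_index[()]].mean())
    return phi, base


def explain_shap(model: ScreeningClassifier, X, background: Optional[np.ndarray] = None,
                 max_background: int = 64) -> ShapReport:
    """Per-sample Shapley attributions for a fitted screening model.

    XGBoost uses its exact TreeSHAP path (margin space); the other
    families use exact interventional Shapley enumeration over all 2^5
    feature subsets against a background sample (probability space).
    Both satisfy the additivity axiom to numerical precision.
    """
    check_is_fitted(model, "estimator_")
    X = np.asarray(X, dtype=float)
    if model.kind == "xgb":
        import xgboost as xgb
        contribs = model.estimator_.get_booster().predict(
            xgb.DMatrix(X), pred_contribs=True)
        phi, base = contribs[:, :-1], float(contribs[0, -1])
        space = "margin"
    else:
        if background is None:
            background = model.X_train_
        if background.shape[0] > max_background:
            rng = np.random.default_rng(model.seed)
            background = background[rng.choice(background.shape[0], max_background,
                                               replace=False)]
        phi, base = _exact_interventional_shap(
            lambda Z: model.estimator_.predict_proba(Z)[:, 1], X, background)
        space = "probability"
    order = np.argsort(-np.abs(phi).mean(axis=0))
    return ShapReport(per_sample=phi, base_value=base,
                      ranking=[FEATURE_ORDER[j] for j in order],
                      output_space=space)


# ---------------------------------------------------------------------------
# record-level convenience wrappers over the estimator
# ---------------------------------------------------------------------------

def train_screening(ds: Dataset, kind: str = "xgb", hpo_budget: int = 50,
                    n_folds: int = 5, seed: int = 0,
                    class_weight=None) -> ScreeningClassifier:
    if hpo_budget < 1:
        raise ValueError("hpo_budget must be >= 1")
    model = ScreeningClassifier(kind=kind, hpo_budget=hpo_budget,
                                n_folds=n_folds, seed=seed,
                                class_weight=class_weight)
    return model.fit(ds.feature_matrix(), ds.labels("glaucoma"))


def predict_proba(model: ScreeningClassifier,
                  records: Sequence[ClinicalRecord]) -> np.ndarray:
    X = np.stack([r.feature_vector() for r in records])
    for i, r in enumerate(records):
        missing = r.missing_features()
        if missing:
            raise ValueError(f"{r.sample_id}: missing feature(s) {missing}; impute first")
    return model.predict_proba(X)[:, 1]
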
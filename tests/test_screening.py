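"""Tier-1 screening: training, operating points, Shapley attribution."""

import numpy as np
import pytest

from multiglau.core.types import FEATURE_ORDER
from multiglau.evaluation import roc_auc
from multiglau.screening import (
    ScreeningClassifier,
    explain_shap,
    select_operating_point,
)


@pytest.fixture(scope="module")
def separable():
    """Cohort where cdr alone separates the classes almost perfectly."""
    rng = np.random.default_rng(42)
    n = 300
    y = rng.integers(0, 2, n)
    X = np.column_stack([
        rng.normal(60, 10, n),               # age: noise
        rng.integers(0, 2, n).astype(float), # gender: noise
        rng.normal(0.7, 0.1, n),             # bcva: noise
        rng.normal(18, 3, n),                # iop: noise
        np.clip(0.35 + 0.35 * y + rng.normal(0, 0.05, n), 0, 1),  # cdr: signal
    ])
    return X, y


@pytest.fixture(scope="module")
def fitted_xgb(separable):
    X, y = separable
    clf = ScreeningClassifier(kind="xgb", hpo_budget=6, n_folds=3, seed=0)
    return clf.fit(X[:200], y[:200])


class TestTraining:
    def test_separable_cohort_reaches_high_auc(self, separable, fitted_xgb):
        X, y = separable
        p = fitted_xgb.predict_proba(X[200:])[:, 1]
        assert roc_auc(p, y[200:]).auc >= 0.95

    def test_permuted_labels_give_chance_auc(self, separable):
        X, y = separable
        rng = np.random.default_rng(0)
        yp = rng.permutation(y)
        clf = ScreeningClassifier(kind="lr", hpo_budget=3, n_folds=3, seed=0)
        clf.fit(X[:200], yp[:200])
        p = clf.predict_proba(X[200:])[:, 1]
        assert 0.4 <= roc_auc(p, yp[200:]).auc <= 0.6

    @pytest.mark.parametrize("kind", ["knn", "svm", "lr", "xgb"])
    def test_tuned_not_worse_than_defaults(self, separable, kind):
        X, y = separable
        tuned = ScreeningClassifier(kind=kind, hpo_budget=6, n_folds=3, seed=1)
        tuned.fit(X, y)
        default = ScreeningClassifier(kind=kind, hpo_budget=0, n_folds=3, seed=1)
        default.fit(X, y)
        assert tuned.cv_auc_ >= default.cv_auc_ - 0.01

    def test_single_class_rejected(self, separable):
        X, _ = separable
        with pytest.raises(ValueError):
            ScreeningClassifier(kind="lr", hpo_budget=2).fit(X[:20], np.ones(20))


class TestPredict:
    def test_probabilities_valid_and_order_preserved(self, separable, fitted_xgb):
        X, _ = separable
        p = fitted_xgb.predict_proba(X)[:, 1]
        assert np.all((p >= 0) & (p <= 1))
        dup = fitted_xgb.predict_proba(np.vstack([X[0], X[0]]))[:, 1]
        assert dup[0] == dup[1]

    def test_missing_feature_named_in_error(self, fitted_xgb):
        X = np.full((2, 5), 0.5)
        X[1, 3] = np.nan
        with pytest.raises(ValueError, match="iop"):
            fitted_xgb.predict_proba(X)

    def test_raising_cdr_does_not_lower_risk(self, fitted_xgb):
        base = np.array([[60.0, 0.0, 0.7, 18.0, 0.3]])
        high = base.copy()
        high[0, 4] = 0.9
        assert (fitted_xgb.predict_proba(high)[0, 1]
                >= fitted_xgb.predict_proba(base)[0, 1])


def brute_force_operating_point(scores, labels, target, mode):
    """Exhaustive oracle over all midpoint thresholds."""
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    best = None
    for t in cands:
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred)[labels == 0].mean()
        if mode == "target_sensitivity" and sens >= target:
            key = (spec, t)
            if best is None or key > best[0]:
                best = (key, t, sens, spec)
        elif mode == "target_specificity" and spec >= target:
            key = (sens, -t)
            if best is None or key > best[0]:
                best = (key, t, sens, spec)
    return best


class TestOperatingPoint:
    def test_perfect_separation(self):
        op = select_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                                    0.9, "target_sensitivity")
        assert op.achieved_sensitivity == 1.0 and op.achieved_specificity == 1.0

    def test_full_sensitivity_threshold_below_min_positive(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        op = select_operating_point(scores, labels, 1.0, "target_sensitivity")
        assert op.threshold <= scores[labels == 1].min()
        assert op.achieved_sensitivity == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(10):
            scores = np.round(rng.random(10), 1)
            labels = rng.integers(0, 2, 10)
            if labels.sum() in (0, 10):
                continue
            for mode in ("target_sensitivity", "target_specificity"):
                op = select_operating_point(scores, labels, 0.7, mode)
                oracle = brute_force_operating_point(scores, labels, 0.7, mode)
                if oracle is not None:
                    assert op.achieved_sensitivity == pytest.approx(oracle[2])
                    assert op.achieved_specificity == pytest.approx(oracle[3])

    def test_specificity_nonincreasing_in_target_sensitivity(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)  # noisy but informative
        specs = [select_operating_point(scores, labels, t, "target_sensitivity")
                 .achieved_specificity for t in (0.80, 0.85, 0.90, 0.95)]
        assert all(a >= b for a, b in zip(specs, specs[1:]))

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            select_operating_point([0.5], [1], 0.0, "target_sensitivity")


class TestShap:
    @pytest.mark.parametrize("kind,budget", [("xgb", 4), ("lr", 2)])
    def test_additivity_axiom(self, separable, kind, budget):
        X, y = separable
        clf = ScreeningClassifier(kind=kind, hpo_budget=budget, n_folds=3, seed=0)
        clf.fit(X[:150], y[:150])
        rep = explain_shap(clf, X[150:170])
        if rep.output_space == "margin":
            outputs = clf.decision_margin(X[150:170])
        else:
            outputs = clf.estimator_.predict_proba(X[150:170])[:, 1]
        assert np.abs(rep.additivity_residual(outputs)).max() < 1e-6

    def test_constant_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.integers(0, 2, n)
        X = np.column_stack([
            np.full(n, 60.0),                 # constant age
            rng.integers(0, 2, n).astype(float),
            rng.normal(0.7, 0.1, n),
            rng.normal(18, 3, n),
            np.clip(0.4 + 0.3 * y + rng.normal(0, 0.05, n), 0, 1),
        ])
        clf = ScreeningClassifier(kind="xgb", hpo_budget=3, n_folds=3, seed=0)
        clf.fit(X, y)
        rep = explain_shap(clf, X[:50])
        assert np.abs(rep.per_sample[:, 0]).max() == 0.0

    def test_planted_signal_ranked_first(self, separable, fitted_xgb):
        X, _ = separable
        rep = explain_shap(fitted_xgb, X[:100])
        assert rep.ranking[0] == "cdr"
        assert set(rep.ranking) == set(FEATURE_ORDER)
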
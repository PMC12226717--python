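"""Metrics, curves and the CV harness, checked against brute-force oracles."""

import math

import numpy as np
import pytest

from multiglau.core.types import Dataset, ImageBundle
from multiglau.evaluation import (
    ConfusionCounts,
    calibration_curve,
    confusion_metrics,
    decision_curve,
    kfold_cv,
    multiclass_metrics,
    roc_auc,
)

from conftest import make_record


def mann_whitney_auc(scores, labels):
    """O(n^2) pairwise oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_arithmetic(self):
        m = confusion_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=0))
        assert m["accuracy"] == pytest.approx(5 / 6)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        m = confusion_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_is_nan_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert math.isnan(m["sensitivity"]) and m["specificity"] == 1.0

    def test_matches_loop_oracle(self, rng):
        pred = rng.integers(0, 2, 200)
        truth = rng.integers(0, 2, 200)
        c = ConfusionCounts.from_predictions(pred, truth)
        tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        m = confusion_metrics(c)
        assert m["accuracy"] == pytest.approx((tp + tn) / 200)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


class TestMulticlass:
    def test_perfect_and_shifted(self):
        truth = np.repeat(np.arange(4), 5)
        perfect = multiclass_metrics(truth, truth)
        assert perfect["accuracy"] == 1.0
        assert perfect["macro_sensitivity"] == 1.0
        assert np.all(np.diag(perfect["confusion_matrix"]) == 5)
        shifted = multiclass_metrics((truth + 1) % 4, truth)
        assert shifted["accuracy"] == 0.0

    def test_matches_per_class_loop_oracle(self, rng):
        pred = rng.integers(0, 4, 100)
        truth = rng.integers(0, 4, 100)
        m = multiclass_metrics(pred, truth)
        sens, spec = [], []
        for c in range(4):
            tp = np.sum((pred == c) & (truth == c))
            fn = np.sum((pred != c) & (truth == c))
            fp = np.sum((pred == c) & (truth != c))
            tn = np.sum((pred != c) & (truth != c))
            sens.append(tp / (tp + fn))
            spec.append(tn / (tn + fp))
        assert m["macro_sensitivity"] == pytest.approx(np.mean(sens), abs=1e-12)
        assert m["macro_specificity"] == pytest.approx(np.mean(spec), abs=1e-12)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            multiclass_metrics([0, 4], [0, 1])


class TestROC:
    def test_perfect_ranking(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5).auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        scores = np.round(rng.random(50), 2)  # rounding forces ties
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-9)

    def test_endpoints_and_monotonicity(self, rng):
        r = roc_auc(rng.random(60), rng.integers(0, 2, 60))
        assert r.x[0] == 0 and r.y[0] == 0 and r.x[-1] == 1 and r.y[-1] == 1
        assert (np.diff(r.x) >= 0).all() and (np.diff(r.y) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCalibration:
    def test_well_calibrated_coin(self, rng):
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=5000)
        labels = (rng.random(5000) < scores).astype(int)
        c = calibration_curve(scores, labels)
        assert np.abs(c.y - c.x).max() < 0.05

    def test_bin_counts_sum_to_n(self, rng):
        c = calibration_curve(rng.random(137), rng.integers(0, 2, 137))
        assert sum(c.extras["bin_counts"]) == 137

    def test_degenerate_single_point(self):
        c = calibration_curve([1.0] * 5, [1] * 5)
        assert len(c.x) == 1 and c.x[0] == 1.0 and c.y[0] == 1.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [1], n_bins=1)


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        d = decision_curve(rng.random(50), rng.integers(0, 2, 50))
        assert np.all(d.reference["treat_none"] == 0)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.array([0] * 30 + [1] * 20)
        scores = labels.astype(float)
        d = decision_curve(scores, labels, thresholds=np.linspace(0.05, 0.95, 19))
        np.testing.assert_allclose(d.y, 0.4, atol=1e-12)

    def test_treat_all_zero_at_prevalence_half(self):
        labels = np.array([0, 1] * 25)
        d = decision_curve(np.linspace(0, 1, 50), labels,
                           thresholds=np.array([0.5]))
        assert d.reference["treat_all"][0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_thresholds_excluded(self, rng):
        with pytest.warns(RuntimeWarning):
            d = decision_curve(rng.random(40), rng.integers(0, 2, 40),
                               thresholds=np.array([0.0, 0.5, 1.0]))
        assert len(d.x) == 1


class TestKFold:
    def _dataset(self, n=50):
        recs = [make_record(i, glaucoma_label=i % 2) for i in range(n)]
        return Dataset(records=recs, bundles=[ImageBundle() for _ in range(n)])

    def test_constant_trainer_has_zero_sd(self):
        ds = self._dataset()
        rep = kfold_cv(ds, k=5,
                       trainer=lambda d: None,
                       evaluator=lambda m, d: {"accuracy": 0.5, "auc": 0.5})
        assert rep.sd["accuracy"] == 0.0 and rep.mean["auc"] == 0.5

    def test_fold_sizes_and_stats_recomputable(self):
        ds = self._dataset(53)
        sizes = []
        rep = kfold_cv(ds, k=5,
                       trainer=lambda d: len(d),
                       evaluator=lambda m, d: (sizes.append(len(d)) or
                                               {"accuracy": len(d) / 53.0}))
        assert max(sizes) - min(sizes) <= 1
        vals = [f["accuracy"] for f in rep.per_fold]
        assert rep.mean["accuracy"] == pytest.approx(np.mean(vals), abs=1e-12)
        assert rep.sd["accuracy"] == pytest.approx(np.std(vals, ddof=1), abs=1e-12)
        assert rep.best_fold_metrics["accuracy"] == max(vals)
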
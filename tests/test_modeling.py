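"""ROC/AUC/Youden against rank-statistic and exhaustive-search oracles;
logistic combination parameter recovery; confusion-matrix arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from bcradiomics.errors import DegenerateLabelsError, SchemaError, \
    ValidationError
from bcradiomics.modeling import (ThresholdModel, evaluate_model,
                                  fit_logistic_combination,
                                  fit_single_feature_model, roc_curve,
                                  youden_cutoff)


def mann_whitney_auc(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def exhaustive_best_j(scores, labels, direction=">="):
    """Max of Se + Sp - 1 over every possible threshold, by enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cands = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    best = -np.inf
    for c in cands:
        pred = scores >= c if direction == ">=" else scores <= c
        se = (pred & (labels == 1)).sum() / max(labels.sum(), 1)
        sp = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        best = max(best, se + sp - 1.0)
    return best


class TestROC:
    def test_perfect_separation_auc_one(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0

    def test_constant_scores_auc_half(self):
        roc = roc_curve([5.0] * 10, [0, 1] * 5)
        assert roc.auc == pytest.approx(0.5)
        # degenerate optimum: the all-one-class operating point with J = 0
        j = roc.youden_sensitivity + roc.youden_specificity - 1.0
        assert j == pytest.approx(0.0)

    def test_auc_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(100):
            n = 50
            scores = rng.choice(rng.normal(size=20), size=n)  # with ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-10)

    def test_auc_invariant_under_increasing_transform(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(scores) + scores**3, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_midpoint_convention(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.youden_threshold == pytest.approx(2.5)
        assert roc.youden_sensitivity == 1.0
        assert roc.youden_specificity == 1.0

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            n = 40
            scores = rng.choice(rng.normal(size=15), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(scores, labels)
            j_model = roc.youden_sensitivity + roc.youden_specificity - 1.0
            assert j_model == pytest.approx(
                exhaustive_best_j(scores, labels), abs=1e-10)
            assert youden_cutoff(roc) == roc.youden_threshold

    def test_lower_direction_example(self):
        # events concentrate at low values; rule "score <= c"
        roc = roc_curve([0.2, 0.3, 0.7, 0.8], [1, 1, 0, 0], direction="<=")
        assert roc.youden_threshold == pytest.approx(0.5)
        j = roc.youden_sensitivity + roc.youden_specificity - 1.0
        assert j == pytest.approx(1.0)


class TestLogisticCombination:
    def test_null_slope_near_zero(self, rng):
        n = 2000
        x = rng.integers(0, 2, size=n).astype(float)
        y = rng.integers(0, 2, size=n)
        model = fit_logistic_combination(pd.DataFrame({"x": x}), y)
        assert abs(model.coef["x"]) < 0.15

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.normal(size=n)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 2.0 * x)))
        y = (rng.random(n) < p).astype(int)
        model = fit_logistic_combination(pd.DataFrame({"x": x}), y)
        assert 1.8 <= model.coef["x"] <= 2.2

    def test_constant_predictor_rejected(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        with pytest.raises(ValidationError):
            fit_logistic_combination(pd.DataFrame({"c": np.ones(50)}), y)

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        y = x.astype(int)
        with pytest.warns(UserWarning):
            model = fit_logistic_combination(pd.DataFrame({"x": x}), y)
        assert model.separation_flag
        assert np.isfinite(model.cutoff)

    def test_intercept_only_behaviour_via_weak_predictor(self, rng):
        # with a predictor carrying no signal the fitted probabilities sit
        # near the prevalence for everyone
        n = 4000
        x = rng.normal(scale=1e-6, size=n) + np.linspace(0, 1e-6, n)
        y = (rng.random(n) < 0.3).astype(int)
        model = fit_logistic_combination(pd.DataFrame({"x": x}), y)
        scores = model.score(pd.DataFrame({"x": x}))
        assert np.allclose(scores, y.mean(), atol=0.02)


class TestEvaluate:
    def test_perfect_predictions(self):
        model = ThresholdModel(predictors=["f"], cutoff=0.5, direction=">=",
                               coef=None)
        table = pd.DataFrame({"f": [0.9, 0.8, 0.1, 0.2]})
        rep = evaluate_model(model, table, [1, 1, 0, 0])
        assert rep.sensitivity == rep.specificity == 1.0
        assert rep.balanced_accuracy == 1.0

    def test_predict_all_positive(self):
        model = ThresholdModel(predictors=["f"], cutoff=-1e9, direction=">=",
                               coef=None)
        table = pd.DataFrame({"f": [0.9, 0.8, 0.1, 0.2]})
        rep = evaluate_model(model, table, [1, 1, 0, 0])
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert rep.balanced_accuracy == 0.5

    def test_hand_contingency_arithmetic(self):
        # TP=10, FP=2, TN=13, FN=5
        values = np.concatenate([np.ones(10), np.ones(2), np.zeros(13),
                                 np.zeros(5)])
        labels = np.concatenate([np.ones(10), np.zeros(2), np.zeros(13),
                                 np.ones(5)]).astype(int)
        model = ThresholdModel(predictors=["f"], cutoff=0.5, direction=">=",
                               coef=None)
        rep = evaluate_model(model, pd.DataFrame({"f": values}), labels)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (10, 2, 13, 5)
        assert rep.sensitivity == pytest.approx(0.667, abs=5e-4)
        assert rep.specificity == pytest.approx(0.867, abs=5e-4)
        assert rep.balanced_accuracy == pytest.approx(0.767, abs=5e-4)
        assert rep.ppv == pytest.approx(0.833, abs=5e-4)
        assert rep.npv == pytest.approx(0.722, abs=5e-4)
        for lo, hi in rep.ci95.values():
            assert 0.0 <= lo <= hi <= 1.0

    def test_counts_sum_to_n_and_bacc_identity(self, rng):
        model = ThresholdModel(predictors=["f"], cutoff=0.0, direction=">=",
                               coef=None)
        vals = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        rep = evaluate_model(model, pd.DataFrame({"f": vals}), labels)
        assert rep.n == 100
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2.0)

    def test_flipping_direction_swaps_se_and_sp(self, rng):
        vals = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        cut = float(np.median(vals)) + 1e-9  # avoid a value on the cut
        m_le = ThresholdModel(predictors=["f"], cutoff=cut, direction="<=",
                              coef=None)
        m_ge = ThresholdModel(predictors=["f"], cutoff=cut, direction=">=",
                              coef=None)
        t = pd.DataFrame({"f": vals})
        r_le = evaluate_model(m_le, t, labels)
        r_ge = evaluate_model(m_ge, t, labels)
        assert r_le.sensitivity == pytest.approx(1.0 - r_ge.sensitivity)
        assert r_le.specificity == pytest.approx(1.0 - r_ge.specificity)

    def test_training_report_reproducible(self, rng):
        vals = rng.normal(size=120)
        labels = (vals + rng.normal(size=120) < 0).astype(int)
        model = fit_single_feature_model(vals, labels, name="f")
        rep = evaluate_model(model, pd.DataFrame({"f": vals}), labels)
        assert rep == model.training_report

    def test_schema_mismatch_raises(self):
        model = ThresholdModel(predictors=["sze"], cutoff=0.5,
                               direction="<=", coef=None)
        with pytest.raises(SchemaError):
            evaluate_model(model, pd.DataFrame({"other": [1.0]}), [1])


def test_single_feature_model_learns_lower_direction(rng):
    # events at low feature values -> direction "<=", as for SZE
    n = 150
    vals = rng.uniform(0, 1, size=n)
    labels = (vals + 0.3 * rng.normal(size=n) < 0.45).astype(int)
    model = fit_single_feature_model(vals, labels, name="SZE")
    assert model.direction == "<="


def test_model_json_roundtrip(tmp_path):
    model = ThresholdModel(predictors=["SZE"], cutoff=0.53, direction="<=",
                           coef=None, metadata={"cohort": "training"})
    path = model.to_json(tmp_path / "m.json")
    back = ThresholdModel.from_json(path)
    t = pd.DataFrame({"SZE": [0.4, 0.6]})
    assert back.predict(t).tolist() == model.predict(t).tolist()
    assert back.direction == "<=" and back.cutoff == 0.53
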
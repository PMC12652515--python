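"""Chemometric models and evaluation statistics."""

import numpy as np
import pytest
from scipy import stats

from beernir.chemometric_models import (
    classification_metrics,
    elm_fit,
    paired_consistency_ttest,
    plsda_fit,
    plsr_fit,
    regression_metrics,
    residual_summary,
    svr_fit,
)


class TestPLSR:
    def test_full_rank_pls_equals_ols(self, linear_regression_data):
        X, y, _ = linear_regression_data
        model = plsr_fit(X, y, max_lv=X.shape[1], folds=5, seed=0)
        A = np.hstack([X, np.ones((len(y), 1))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols_pred = A @ beta
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-6)

    def test_lv_count_chosen_by_press(self, linear_regression_data):
        X, y, _ = linear_regression_data
        model = plsr_fit(X, y, max_lv=10, folds=5, seed=0)
        best = min(model.press_by_lv, key=lambda lv: (model.press_by_lv[lv], lv))
        assert model.n_components == best

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            plsr_fit(np.random.default_rng(0).normal(size=(20, 5)), np.ones(20))


class TestPLSDA:
    def test_separable_classes_reach_perfect_accuracy(self, rng):
        n = 30
        X = np.vstack([
            rng.normal(0, 0.1, size=(n, 4)) + off
            for off in ([0, 0, 0, 0], [3, 0, 0, 0], [0, 3, 0, 0])
        ])
        labels = np.repeat(["a", "b", "c"], n)
        model = plsda_fit(X, labels, max_lv=4, folds=5, seed=0)
        assert np.mean(model.predict(X) == labels) == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            plsda_fit(rng.normal(size=(10, 3)), np.repeat("a", 10))

    def test_lv_ties_resolve_to_fewer_components(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 3)), rng.normal(5, 0.05, (20, 3))])
        labels = np.repeat(["a", "b"], 20)
        model = plsda_fit(X, labels, max_lv=3, folds=5, seed=0)
        assert model.n_components == 1  # everything beyond LV1 ties at 100%


class TestSVR:
    def test_fits_smooth_nonlinear_function(self, rng):
        F = rng.uniform(-1, 1, size=(80, 2))
        y = np.sin(2 * F[:, 0]) + F[:, 1] ** 2
        model = svr_fit(F, y, folds=5, seed=0)
        pred = model.predict(F)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.15

    def test_standardization_stored(self, rng):
        F = rng.normal(size=(40, 3)) * 100 + 50
        y = F[:, 0] / 100.0
        model = svr_fit(F, y, folds=5, seed=0)
        np.testing.assert_allclose(model.mean, F.mean(axis=0))

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            svr_fit(rng.normal(size=(20, 2)), rng.normal(size=20),
                    grid={"C": [], "gamma": [1], "epsilon": [0.1]})


class TestELM:
    def test_identity_activation_reduces_to_linear_least_squares(self, rng):
        F = rng.normal(size=(50, 4))
        y = F @ np.array([1.0, -2.0, 0.5, 3.0]) + 4.0
        grid = {"hidden_units": [8], "weight_range": [1.0], "bias_range": [1.0]}
        model = elm_fit(F, y, grid=grid, folds=5, seed=0, activation="identity")
        # a linear hidden layer of width >= d spans the same function space
        np.testing.assert_allclose(model.predict(F), y, atol=1e-6)

    def test_nested_hidden_bases_across_grid(self, rng):
        # the weights for h hidden units are a prefix of the weights for the
        # largest width, so grid comparisons reuse the same random basis
        F = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        g_small = {"hidden_units": [10], "weight_range": [0.5], "bias_range": [0.5]}
        g_large = {"hidden_units": [10, 40], "weight_range": [0.5], "bias_range": [0.5]}
        m_small = elm_fit(F, y, grid=g_small, folds=5, seed=3)
        m_large = elm_fit(F, y, grid=g_large, folds=5, seed=3)
        h = m_small.W.shape[0]
        np.testing.assert_allclose(m_small.W, m_large.W[:h] if m_large.W.shape[0] >= h else m_small.W)

    def test_sigmoid_fits_nonlinearity(self, rng):
        F = rng.uniform(-1, 1, size=(80, 1))
        y = np.tanh(3 * F[:, 0])
        model = elm_fit(F, y, folds=5, seed=0)
        assert np.sqrt(np.mean((model.predict(F) - y) ** 2)) < 0.1


class TestRegressionMetrics:
    def test_formulas_match_hand_computation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([1.1, 1.9, 3.2, 3.8])
        m = regression_metrics(y, p, {"all": np.arange(4)})
        resid = y - p
        rmse = np.sqrt(np.mean(resid**2))
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        row = m.loc["all"]
        assert row["RMSE"] == pytest.approx(rmse)
        assert row["R2"] == pytest.approx(r2)
        assert row["rRMSE"] == pytest.approx(100 * rmse / y.mean())
        assert row["RPD"] == pytest.approx(np.std(y, ddof=1) / rmse)

    def test_subsets_evaluated_independently(self):
        y = np.array([1.0, 2.0, 10.0, 20.0])
        p = y + 0.1
        m = regression_metrics(y, p, {"lo": np.array([0, 1]), "hi": np.array([2, 3])})
        assert m.loc["lo", "rRMSE"] == pytest.approx(100 * 0.1 / 1.5)
        assert m.loc["hi", "rRMSE"] == pytest.approx(100 * 0.1 / 15.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            regression_metrics(np.ones(3), np.ones(3), {"none": np.array([], int)})


class TestClassificationMetrics:
    def test_perfect_prediction_scores_100(self):
        labels = np.array(["a", "b", "a", "b"])
        m = classification_metrics(labels, labels, {"all": np.arange(4)})
        for k in ("ACC", "Precision", "Recall", "MF1", "WF1"):
            assert m["all"][k] == pytest.approx(100.0)

    def test_confusion_matrix_counts(self):
        ref = np.array(["a", "a", "b", "b"])
        pred = np.array(["a", "b", "b", "b"])
        m = classification_metrics(ref, pred, {"all": np.arange(4)})
        cmat = m["all"]["confusion"]
        assert cmat.loc["a", "a"] == 1
        assert cmat.loc["a", "b"] == 1
        assert cmat.loc["b", "b"] == 2
        assert m["all"]["ACC"] == pytest.approx(75.0)

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="outside reference"):
            classification_metrics(
                np.array(["a", "b"]), np.array(["a", "z"]), {"all": np.arange(2)}
            )


class TestPairedTTest:
    def test_matches_scipy(self, rng):
        y = rng.normal(size=30)
        p = y + rng.normal(0, 0.1, size=30)
        reject, pval = paired_consistency_ttest(y, p)
        _, ref = stats.ttest_rel(p, y)
        assert pval == pytest.approx(ref)

    def test_identical_vectors_do_not_reject(self):
        y = np.arange(10.0)
        reject, pval = paired_consistency_ttest(y, y.copy())
        assert not reject and pval == 1.0

    def test_biased_predictions_reject(self, rng):
        y = rng.normal(size=50)
        reject, pval = paired_consistency_ttest(y, y + 1.0)
        assert reject and pval < 1e-6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_consistency_ttest(np.array([1.0]), np.array([1.0]))


class TestResidualSummary:
    def test_fields(self, rng):
        y = rng.normal(size=200)
        p = y + rng.normal(0, 0.1, size=200)
        s = residual_summary(y, p, threshold=0.2)
        assert s["min"] <= s["interval95"][0] < s["interval95"][1] <= s["max"]
        assert 80.0 < s["share_within"] <= 100.0
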
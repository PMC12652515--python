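"""Deep feature extractors: backprop correctness, training and BOA."""

import numpy as np
import pytest

from beernir.deepfeat import (
    ATTENTION_HEADS,
    ATTENTION_KEY_DIM,
    BOAParam,
    ExtractorConfig,
    boa_optimize,
    build_network,
    default_space,
    extract_features,
    train_extractor,
    tune_extractor,
    _fit_network,
    _loss_and_grad,
)

TINY = dict(
    numResponses=6,
    FiltSize=5,
    numChannels=4,
    numHiddenUnits=8,
    MaxEpochs=3,
    InitialLearnRate=1e-3,
    LearnRateDropPeriod=50,
    LearnRateDropFactor=0.8,
    L2Regularization=0.0,
)


def _numeric_grad_check(arch, task, p=24, n=5, eps=1e-6, tol=5e-5):
    cfg = ExtractorConfig(arch=arch, task=task, **TINY)
    rng = np.random.default_rng(0)
    X3 = rng.normal(size=(n, p, 1))
    if task == "classify":
        target = rng.integers(0, 2, size=n)
    else:
        target = rng.normal(size=n)
    net = build_network(cfg, p, seed=0)
    out = net.forward(X3)
    _, g = _loss_and_grad(out, target, cfg.task)
    net.backward(g)
    worst = 0.0
    for p_arr, g_arr in net.parameters():
        flat = p_arr.ravel()
        idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = _loss_and_grad(net.forward(X3), target, cfg.task)
            flat[i] = orig - eps
            lm, _ = _loss_and_grad(net.forward(X3), target, cfg.task)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - g_arr.ravel()[i]))
    assert worst < tol, f"max abs gradient error {worst}"


class TestConfig:
    def test_unknown_arch_and_task_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            ExtractorConfig(arch="transformer")
        with pytest.raises(ValueError, match="task"):
            ExtractorConfig(task="reg_ph")

    def test_drop_factor_bounds(self):
        with pytest.raises(ValueError):
            ExtractorConfig(LearnRateDropFactor=1.5)

    def test_attention_geometry_constants(self):
        assert ATTENTION_HEADS == 4
        assert ATTENTION_KEY_DIM == 40


class TestBackprop:
    @pytest.mark.parametrize("arch", ["cnn", "lstm", "cnn_lstm"])
    def test_regression_gradients_match_finite_differences(self, arch):
        _numeric_grad_check(arch, "reg_alcohol")

    def test_classification_gradients_match_finite_differences(self):
        _numeric_grad_check("cnn_lstm", "classify")


class TestTraining:
    def _data(self, n=30, p=24, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = X[:, 3] * 2.0 + 1.0  # noiseless linear signal
        return X, y

    def test_deterministic_objective(self):
        X, y = self._data()
        cfg = ExtractorConfig(arch="cnn_lstm", task="reg_alcohol", **TINY)
        _, a = train_extractor(cfg, X, y, folds=3, seed=1)
        _, b = train_extractor(cfg, X, y, folds=3, seed=1)
        assert a == b

    def test_training_beats_an_untrained_model(self):
        X, y = self._data(n=40)
        trained = dict(TINY, MaxEpochs=30, InitialLearnRate=3e-3)
        cfg_t = ExtractorConfig(arch="cnn", task="reg_alcohol", **trained)
        # an (effectively) untrained model: one epoch at a vanishing rate
        cfg_u = ExtractorConfig(
            arch="cnn", task="reg_alcohol",
            **dict(TINY, MaxEpochs=1, InitialLearnRate=1e-12),
        )
        _, obj_t = train_extractor(cfg_t, X, y, folds=3, seed=0)
        _, obj_u = train_extractor(cfg_u, X, y, folds=3, seed=0)
        assert obj_t < obj_u

    def test_classification_reaches_100_within_50_epochs(self, rng):
        n = 20
        X = np.vstack([
            rng.normal(0, 0.05, size=(n, 24)),
            rng.normal(1.2, 0.05, size=(n, 24)),
            rng.normal(-1.2, 0.05, size=(n, 24)),
        ])
        labels = np.repeat(["a", "b", "c"], n)
        cfg = ExtractorConfig(
            arch="cnn_lstm", task="classify",
            **dict(TINY, MaxEpochs=50, InitialLearnRate=3e-3),
        )
        model, acccv = train_extractor(cfg, X, labels, folds=3, seed=0)
        assert acccv == 100.0
        assert np.mean(model.predict(X) == labels) == 1.0

    def test_feature_matrix_shape_and_determinism(self):
        X, y = self._data()
        cfg = ExtractorConfig(arch="cnn_lstm", task="reg_alcohol", **TINY)
        model, _ = train_extractor(cfg, X, y, folds=3, seed=0)
        F1 = extract_features(model, X)
        F2 = extract_features(model, X)
        assert F1.shape == (30, TINY["numResponses"])
        np.testing.assert_array_equal(F1, F2)

    def test_wavelength_count_mismatch_rejected(self):
        X, y = self._data()
        cfg = ExtractorConfig(arch="cnn", task="reg_alcohol", **TINY)
        model, _ = train_extractor(cfg, X, y, folds=3, seed=0)
        with pytest.raises(ValueError, match="wavelengths"):
            extract_features(model, X[:, :-1])

    def test_divergence_error_echoes_config(self):
        X, y = self._data()
        y = y * 1e6  # force a huge-loss regime with an absurd learning rate
        cfg = ExtractorConfig(
            arch="lstm", task="reg_alcohol",
            **dict(TINY, InitialLearnRate=1e-2, MaxEpochs=5),
        )
        # the standardized target keeps this finite; instead corrupt input
        Xbad = X * 1e8
        try:
            _fit_network(
                cfg, Xbad[:, :, None], (y - y.mean()) / y.std(), seed=0
            )
        except RuntimeError as e:
            assert "ExtractorConfig" in str(e)


class TestBOA:
    def test_param_from_unit_scales(self):
        lin = BOAParam(0.0, 10.0, "linear")
        assert lin.from_unit(0.5) == pytest.approx(5.0)
        log = BOAParam(1e-4, 1e-2, "log")
        assert log.from_unit(0.5) == pytest.approx(1e-3)
        integer = BOAParam(3, 15, "integer")
        assert integer.from_unit(0.0) == 3 and isinstance(integer.from_unit(0.3), int)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BOAParam(1.0, 1.0)
        with pytest.raises(ValueError):
            BOAParam(-1.0, 1.0, "log")
        with pytest.raises(ValueError):
            BOAParam(0.0, 1.0, "cubic")

    def test_finds_quadratic_minimum_within_40_evals(self):
        space = {"x": BOAParam(0.0, 1.0, "linear")}
        res = boa_optimize(
            space, lambda p: (p["x"] - 0.3) ** 2, n_iter=40, n_init=5, seed=0
        )
        assert abs(res.best_params["x"] - 0.3) < 0.05
        assert len(res.trace) == 40

    def test_trace_is_monotone_incumbent(self):
        space = {"x": BOAParam(-1.0, 1.0, "linear")}
        res = boa_optimize(space, lambda p: np.sin(5 * p["x"]), n_iter=15, n_init=4,
                           seed=1)
        assert np.all(np.diff(res.trace) <= 1e-12)

    def test_maximization_flips_the_direction(self):
        space = {"x": BOAParam(0.0, 1.0, "linear")}
        res = boa_optimize(
            space, lambda p: -((p["x"] - 0.7) ** 2), n_iter=30, n_init=5, seed=0,
            maximize=True,
        )
        assert abs(res.best_params["x"] - 0.7) < 0.1
        assert np.all(np.diff(res.trace) >= -1e-12)

    def test_failed_evaluations_are_recorded_not_fatal(self):
        calls = []

        def objective(p):
            calls.append(p["x"])
            return np.nan if p["x"] < 0.5 else p["x"]

        space = {"x": BOAParam(0.0, 1.0, "linear")}
        res = boa_optimize(space, objective, n_iter=10, n_init=4, seed=0)
        assert res.evaluations["objective"].isna().any()
        assert np.isfinite(res.best_objective)

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            boa_optimize({"x": BOAParam(0, 1)}, lambda p: 0.0, n_iter=3, n_init=5)

    def test_default_space_brackets_published_optima(self):
        space = default_space("cnn_lstm")
        # printed optima: numResponses 74/47/21, FiltSize up to 15,
        # hidden units up to 128, epochs up to 400
        assert space["numResponses"].low <= 21 <= 74 <= space["numResponses"].high
        assert space["MaxEpochs"].high == 400
        assert space["numHiddenUnits"].high == 128
        assert "FiltSize" in space and "numChannels" in space
        assert "FiltSize" not in default_space("lstm")
        assert "numHiddenUnits" not in default_space("cnn")


class TestTune:
    def test_tune_extractor_respects_caps_and_improves(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(36, 24))
        y = X[:, 5] * 3.0
        model, obj, res = tune_extractor(
            "cnn", "reg_alcohol", X, y, n_iter=3, n_init=2, folds=3, seed=0,
            max_epochs_cap=21, max_channels_cap=4,
        )
        assert model.config.MaxEpochs <= 21
        assert model.config.numChannels <= 4
        assert len(res.trace) == 3
        assert np.isfinite(obj)
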
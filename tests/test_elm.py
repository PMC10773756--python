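import numpy as np
import pytest
from scipy.special import expit

from driftstream import (
    ConfigurationError,
    FormatError,
    LabeledSeriesSet,
    PreprocessorConfig,
    elm_forward,
    fit_elm,
    init_elm,
    preprocess_window,
    train_preprocessor,
)
from driftstream.elm import _autoregression_rows, load_elm, save_elm


class TestInit:
    def test_default_shapes(self):
        model = init_elm(5, 32, 1, seed=0)
        assert model.W.shape == (32, 5)
        assert model.b.shape == (32,)
        assert model.beta.shape == (32, 1)

    def test_weights_in_unit_interval(self):
        model = init_elm(5, 32, 1, seed=0)
        assert model.W.min() >= -1.0 and model.W.max() <= 1.0
        assert model.b.min() >= -1.0 and model.b.max() <= 1.0

    def test_seed_determinism(self):
        a = init_elm(seed=42)
        b = init_elm(seed=42)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.b, b.b)

    def test_single_hidden_node(self):
        model = init_elm(2, 1, 1, seed=0)
        assert model.W.shape == (1, 2)

    def test_bad_dims(self):
        with pytest.raises(ConfigurationError):
            init_elm(0, 4, 1)


class TestForward:
    def test_zero_beta_gives_zero(self, rng):
        model = init_elm(3, 8, 1, seed=1)
        out = elm_forward(model, rng.standard_normal((10, 3)))
        assert np.array_equal(out, np.zeros((10, 1)))

    def test_batch_consistency(self, rng):
        model = init_elm(3, 8, 1, seed=1)
        model = fit_elm(model, rng.standard_normal((20, 3)), rng.standard_normal(20))
        x = rng.standard_normal((2, 3))
        batch = elm_forward(model, x)
        np.testing.assert_allclose(batch[0], elm_forward(model, x[0])[0], atol=1e-15)
        np.testing.assert_allclose(batch[1], elm_forward(model, x[1])[0], atol=1e-15)

    def test_hand_computed_two_node_case(self):
        """Manual sigmoid arithmetic for a fixed tiny network."""
        model = init_elm(2, 2, 1, seed=0)
        W = np.array([[0.5, -1.0], [2.0, 0.25]])
        b = np.array([0.1, -0.2])
        beta = np.array([[1.5], [-0.5]])
        model = model.__class__(W=W, b=b, beta=beta, input_nums=2, hidden_nums=2,
                                output_nums=1, seed=0)
        x = np.array([0.3, 0.7])
        h0 = 1 / (1 + np.exp(-(0.5 * 0.3 - 1.0 * 0.7 + 0.1)))
        h1 = 1 / (1 + np.exp(-(2.0 * 0.3 + 0.25 * 0.7 - 0.2)))
        expected = 1.5 * h0 - 0.5 * h1
        assert elm_forward(model, x)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_width_mismatch(self, rng):
        model = init_elm(3, 4, 1)
        with pytest.raises(FormatError):
            elm_forward(model, rng.standard_normal((5, 4)))


class TestFit:
    def test_zero_targets_give_zero_beta(self, rng):
        model = init_elm(3, 6, 1, seed=2)
        fitted = fit_elm(model, rng.standard_normal((30, 3)), np.zeros(30))
        np.testing.assert_allclose(fitted.beta, 0.0, atol=1e-12)

    def test_random_weights_frozen_by_fit(self, rng):
        model = init_elm(3, 6, 1, seed=2)
        fitted = fit_elm(model, rng.standard_normal((30, 3)), rng.standard_normal(30))
        assert np.array_equal(fitted.W, model.W)
        assert np.array_equal(fitted.b, model.b)

    def test_matches_lstsq_oracle(self, rng):
        for trial in range(30):
            model = init_elm(4, 8, 2, seed=trial)
            x = rng.standard_normal((60, 4))
            t = rng.standard_normal((60, 2))
            fitted = fit_elm(model, x, t, regularization=0.0)
            H = expit(x @ model.W.T + model.b)
            oracle = np.linalg.lstsq(H, t, rcond=None)[0]
            np.testing.assert_allclose(fitted.beta, oracle, atol=1e-6)

    def test_ridge_close_to_exact_solution_when_well_conditioned(self, rng):
        model = init_elm(3, 5, 1, seed=0)
        x = rng.standard_normal((200, 3))
        t = rng.standard_normal((200, 1))
        H = expit(x @ model.W.T + model.b)
        assert np.linalg.cond(H) < 1e3
        ridge = fit_elm(model, x, t, regularization=1e-8)
        exact = fit_elm(model, x, t, regularization=0.0)
        np.testing.assert_allclose(ridge.beta, exact.beta, atol=1e-6)

    def test_residual_orthogonality(self, rng):
        for trial in range(30):
            model = init_elm(4, 8, 1, seed=100 + trial)
            x = rng.standard_normal((50, 4))
            t = rng.standard_normal((50, 1))
            fitted = fit_elm(model, x, t, regularization=0.0)
            H = expit(x @ model.W.T + model.b)
            resid = H.T @ (H @ fitted.beta - t)
            assert np.abs(resid).max() <= 1e-6

    def test_row_mismatch(self, rng):
        model = init_elm(3, 4, 1)
        with pytest.raises(FormatError):
            fit_elm(model, rng.standard_normal((5, 3)), rng.standard_normal(4))


class TestTrainPreprocessor:
    def test_constant_series_predicts_constant(self):
        data = LabeledSeriesSet(np.full((4, 20), 0.6), np.zeros(4, dtype=int))
        cfg = PreprocessorConfig()
        model = train_preprocessor(data, cfg, seed=0)
        inputs, targets = _autoregression_rows(data.values, cfg.context)
        preds = elm_forward(model, inputs)
        assert float(np.mean((preds - targets) ** 2)) <= 1e-4

    def test_training_row_count(self, rng):
        s, l, c = 7, 30, 5
        data = LabeledSeriesSet(rng.random((s, l)), np.zeros(s, dtype=int))
        inputs, targets = _autoregression_rows(data.values, c)
        assert inputs.shape == (s * (l - c), c)
        assert targets.shape == (s * (l - c), 1)

    def test_sinusoid_mse_bounded_by_noise(self, rng):
        t = np.arange(64) / 64
        noise_sd = 0.05
        values = np.sin(2 * np.pi * 2 * t) + noise_sd * rng.standard_normal((20, 64))
        data = LabeledSeriesSet(values, np.zeros(20, dtype=int))
        cfg = PreprocessorConfig()
        model = train_preprocessor(data, cfg, seed=1)
        inputs, targets = _autoregression_rows(data.values, cfg.context)
        mse = float(np.mean((elm_forward(model, inputs) - targets) ** 2))
        assert mse <= 10 * noise_sd**2

    def test_short_series_rejected(self):
        data = LabeledSeriesSet(np.random.rand(3, 5), np.zeros(3, dtype=int))
        with pytest.raises(ConfigurationError):
            train_preprocessor(data, PreprocessorConfig(context=5))

    def test_reproducible(self, rng):
        data = LabeledSeriesSet(rng.random((5, 20)), np.zeros(5, dtype=int))
        a = train_preprocessor(data, PreprocessorConfig(), seed=9)
        b = train_preprocessor(data, PreprocessorConfig(), seed=9)
        assert np.array_equal(a.beta, b.beta)


class TestPreprocessWindow:
    def make_window(self, rng, s=10, l=32):
        return LabeledSeriesSet(rng.random((s, l)), rng.integers(0, 2, s), ("a", "b"))

    def test_blend_zero_is_identity(self, rng):
        window = self.make_window(rng)
        model = train_preprocessor(window, PreprocessorConfig(), seed=0)
        out = preprocess_window(model, window, PreprocessorConfig(blend=0.0))
        assert out == window

    def test_shape_and_labels_preserved(self, rng):
        window = self.make_window(rng)
        model = train_preprocessor(window, PreprocessorConfig(), seed=0)
        out = preprocess_window(model, window, PreprocessorConfig(blend=1.0))
        assert out.values.shape == window.values.shape
        assert np.array_equal(out.labels, window.labels)
        assert out.class_names == window.class_names

    def test_head_points_pass_through(self, rng):
        window = self.make_window(rng)
        cfg = PreprocessorConfig(blend=1.0)
        model = train_preprocessor(window, cfg, seed=0)
        out = preprocess_window(model, window, cfg)
        assert np.array_equal(out.values[:, : cfg.context], window.values[:, : cfg.context])

    def test_narrow_window_rejected(self, rng):
        window = LabeledSeriesSet(rng.random((3, 4)), np.zeros(3, dtype=int))
        model = init_elm(5, 8, 1)
        with pytest.raises(ConfigurationError):
            preprocess_window(model, window, PreprocessorConfig(context=5))

    def test_deterministic(self, rng):
        window = self.make_window(rng)
        cfg = PreprocessorConfig(blend=0.7)
        model = train_preprocessor(window, cfg, seed=4)
        a = preprocess_window(model, window, cfg)
        b = preprocess_window(model, window, cfg)
        assert a == b


class TestSerialization:
    def test_roundtrip(self, rng, tmp_path):
        data = LabeledSeriesSet(rng.random((5, 20)), np.zeros(5, dtype=int))
        model = train_preprocessor(data, PreprocessorConfig(), seed=3)
        path = str(tmp_path / "elm.npz")
        save_elm(model, path)
        back = load_elm(path)
        assert np.array_equal(back.W, model.W)
        assert np.array_equal(back.beta, model.beta)
        assert back.input_nums == model.input_nums
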
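"""Convolutional classifier: construction, training, persistence."""

import numpy as np
import pytest

from virokind.cnn import (ClassifierConfig, TrainedClassifier, build_model,
                          categorical_cross_entropy)
from virokind.sgt import PatternMatrix


class TestBuildModel:
    def test_default_parameter_count_matches_closed_form(self):
        model = build_model(ClassifierConfig())
        expected = ((7 * 7 * 1 + 1) * 128        # conv1
                    + (7 * 7 * 128 + 1) * 128    # conv2
                    + (16 * 16 * 128 + 1) * 64   # dense1 (64 -> 32 -> 16 pooling)
                    + (64 + 1) * 2)              # dense2
        assert model.n_parameters == expected

    def test_zero_matrix_scores_sum_to_one(self):
        model = build_model(ClassifierConfig())
        p = model.predict_proba(np.zeros((1, 64, 64), dtype=np.float32))
        assert p.shape == (1, 2)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("field,value", [
        ("n_filters", 0), ("dropout_p", 1.0), ("n_classes", 1),
        ("learning_rate", 0.0), ("kappa", -1.0), ("input_gain", 0.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = ClassifierConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            build_model(cfg)

    def test_class_name_count_must_match(self):
        with pytest.raises(ValueError, match="class names"):
            build_model(ClassifierConfig(), class_names=("a", "b", "c"))


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert categorical_cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln2(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        assert categorical_cross_entropy(y, p) == pytest.approx(np.log(2), abs=1e-9)

    def test_loss_nonnegative_random(self):
        rng = np.random.default_rng(0)
        y = np.eye(2)[rng.integers(0, 2, 20)]
        p = rng.dirichlet((1, 1), size=20)
        assert categorical_cross_entropy(y, p) >= 0.0


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Float64 central differences on a small config covering both
        convolution lowerings (one-channel im2col and multi-channel
        shifted GEMM)."""
        cfg = ClassifierConfig(n_filters=20, dense_units=5, dropout_p=0.0,
                               seed=7, input_side=16)
        model = build_model(cfg)
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(0)
        x = rng.random((3, 16, 16))
        y = np.eye(2)[[0, 1, 0]].astype(np.float64)
        _, cache = model._forward(x, training=False)
        grads = model._backward(y, cache)

        def loss():
            p, _ = model._forward(x, training=False)
            return categorical_cross_entropy(y, p)

        pick = np.random.default_rng(1)
        for key, param in model.params.items():
            flat = param.ravel()
            for i in pick.choice(flat.size, size=min(5, flat.size), replace=False):
                h = 1e-6
                old = flat[i]
                flat[i] = old + h
                lp = loss()
                flat[i] = old - h
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key].ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-9), key


class TestPredict:
    def test_rows_sum_to_one_and_bounded(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(0).random((7, 64, 64)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (7, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all() and (p <= 1).all()

    def test_duplicated_inputs_identical_scores(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(1).random((1, 64, 64)).astype(np.float32)
        p = model.predict_proba(np.vstack([x, x]))
        assert (p[0] == p[1]).all()

    def test_permutation_equivariance(self, tiny_config):
        model = build_model(tiny_config)
        x = np.random.default_rng(2).random((5, 64, 64)).astype(np.float32)
        p = model.predict_proba(x)
        perm = [3, 0, 4, 1, 2]
        np.testing.assert_array_equal(model.predict_proba(x[perm]), p[perm])

    def test_kappa_mismatch_rejected(self, tiny_config):
        model = build_model(tiny_config)  # kappa = 1.0
        mat = PatternMatrix(weights=np.zeros((64, 64)), kappa=2.0, sequence_id="q")
        with pytest.raises(ValueError, match="kappa"):
            model.predict_proba([mat])


class TestTraining:
    @staticmethod
    def _separable_batch(n=128, seed=0):
        """Two classes of 64x64 matrices with mass in opposite corners."""
        rng = np.random.default_rng(seed)
        x = rng.random((n, 64, 64)).astype(np.float32) * 0.01
        y = np.zeros((n, 2), dtype=np.float32)
        for i in range(n):
            cls = i % 2
            if cls == 0:
                x[i, :8, :8] += 0.5
            else:
                x[i, -8:, -8:] += 0.5
            y[i, cls] = 1.0
        return x, y

    def test_separable_classes_reach_high_accuracy(self):
        cfg = ClassifierConfig(n_filters=4, dense_units=8, epochs=10,
                               dropout_p=0.0, seed=0, input_gain=1.0)
        model = build_model(cfg)
        x, y = self._separable_batch()
        history = model.fit(x, y)
        assert history["accuracy"][-1] >= 0.95

    def test_loss_trend_non_increasing(self):
        cfg = ClassifierConfig(n_filters=4, dense_units=8, epochs=10,
                               dropout_p=0.0, seed=0, input_gain=1.0)
        model = build_model(cfg)
        x, y = self._separable_batch()
        loss = model.fit(x, y)["loss"]
        # trend: each epoch at most 10% above the best seen so far
        best = loss[0]
        for v in loss[1:]:
            assert v <= best * 1.10 + 1e-6
            best = min(best, v)

    def test_same_seed_reproduces_history(self, tiny_config):
        x, y = self._separable_batch(n=16, seed=3)
        h1 = build_model(tiny_config).fit(x, y)
        h2 = build_model(tiny_config).fit(x, y)
        np.testing.assert_allclose(h1["loss"], h2["loss"], atol=1e-4)

    def test_label_shape_validated(self, tiny_config):
        model = build_model(tiny_config)
        x = np.zeros((4, 64, 64), dtype=np.float32)
        with pytest.raises(ValueError, match="one-hot"):
            model.fit(x, np.array([0, 1, 0, 1]).reshape(4, 1))

    def test_input_shape_validated(self, tiny_config):
        model = build_model(tiny_config)
        with pytest.raises(ValueError, match="64"):
            model.fit(np.zeros((4, 32, 32), dtype=np.float32), np.eye(2)[[0, 1, 0, 1]])


class TestPersistence:
    def test_save_load_roundtrip_identical_predictions(self, tiny_config, tmp_path):
        model = build_model(tiny_config)
        x = np.random.default_rng(4).random((3, 64, 64)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "weights.npz"
        model.save(path)
        loaded = TrainedClassifier.load(path)
        assert loaded.config == model.config
        assert loaded.class_names == model.class_names
        np.testing.assert_array_equal(loaded.predict_proba(x), before)

    def test_corrupted_file_error_names_path(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a weights file")
        with pytest.raises(ValueError, match="junk.npz"):
            TrainedClassifier.load(path)

    def test_loaded_kappa_guards_encoding(self, tiny_config, tmp_path):
        tiny_config.kappa = 2.0
        model = build_model(tiny_config)
        path = tmp_path / "k2.npz"
        model.save(path)
        loaded = TrainedClassifier.load(path)
        mat = PatternMatrix(weights=np.zeros((64, 64)), kappa=1.0, sequence_id="q")
        with pytest.raises(ValueError, match="kappa"):
            loaded.predict_proba([mat])
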
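"""The numpy CNN: gradients, shapes, training contracts."""

import numpy as np
import pytest

from eegnda.errors import ConfigurationError, SizingError
from eegnda.model import CNN, ModelSpec, TrainConfig, build_model, predict, train
from eegnda.sampling import WindowBatch


def tiny_spec(**overrides):
    base = dict(
        window_length=40,
        n_channels=2,
        conv_filters=(2, 3, 4),
        conv_kernels=(3, 3, 3),
        dense_widths=(5,),
        n_classes=6,
        dropout=0.0,
        seed=1,
    )
    base.update(overrides)
    return ModelSpec(**base)


def make_batch(data, labels):
    return WindowBatch(
        data=data,
        labels=labels,
        starts=np.zeros(len(data), dtype=int),
        offset=0.5,
    )


class TestArchitecture:
    def test_default_filter_kernel_schedule(self):
        spec = ModelSpec(window_length=200)
        assert spec.conv_filters == (32, 64, 128)
        assert spec.kernel_sizes == (3, 5, 7)
        assert spec.pool_size == 2

    def test_output_is_probability_vector(self):
        net = build_model(tiny_spec())
        x = np.random.default_rng(0).standard_normal((4, 2, 40))
        probs, _ = net.forward(x)
        assert probs.shape == (4, 6)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_parameter_count_matches_shape_walk(self):
        """Hand-computed layer-shape arithmetic for the default net."""
        n = 200
        net = build_model(ModelSpec(window_length=n, seed=0))
        l1 = (n - 3 + 1) // 2          # 99
        l2 = (l1 - 5 + 1) // 2         # 47
        l3 = (l2 - 7 + 1) // 2         # 20
        expected = (
            (32 * 32 * 3 + 32) + 2 * 32     # conv1 + bn1 gamma/beta
            + (64 * 32 * 5 + 64) + 2 * 64   # conv2 + bn2
            + (128 * 64 * 7 + 128) + 2 * 128  # conv3 + bn3
            + (128 * l3 * 128 + 128)        # dense 1
            + (128 * 64 + 64)               # dense 2
            + (64 * 6 + 6)                  # output head
        )
        assert net.parameter_count() == expected

    def test_too_short_window_names_offending_stage(self):
        with pytest.raises(SizingError, match="stage"):
            build_model(ModelSpec(window_length=12, seed=0)).spec

    def test_identical_seeds_identical_weights(self):
        a = build_model(tiny_spec(seed=9))
        b = build_model(tiny_spec(seed=9))
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_filters_must_increase(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(window_length=100, conv_filters=(64, 32, 128))


class TestGradients:
    def test_analytic_gradients_match_numerical(self):
        """Central-difference check of every parameter gradient (float64)."""
        net = CNN(tiny_spec(), dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 2, 40))
        y = (rng.random((3, 6)) < 0.4).astype(float)
        _, grads = net.loss_and_grads(x, y)
        h = 1e-6
        for key, p in net.params.items():
            flat = p.ravel()
            num = np.zeros_like(flat)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                lp, _ = net.loss_and_grads(x, y)
                flat[i] = orig - h
                lm, _ = net.loss_and_grads(x, y)
                flat[i] = orig
                num[i] = (lp - lm) / (2 * h)
            ana = grads[key].ravel()
            scale = max(np.abs(num).max(), np.abs(ana).max(), 1e-4)
            assert np.abs(num - ana).max() / scale < 1e-5, key

    def test_dropout_gradient_consistent_with_fixed_mask(self):
        """With a reseeded rng the dropout mask repeats, so gradients are
        deterministic too."""
        net = CNN(tiny_spec(dropout=0.3), dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 2, 40))
        y = (rng.random((3, 6)) < 0.4).astype(float)
        l1, g1 = net.loss_and_grads(x, y, rng=np.random.default_rng(7))
        l2, g2 = net.loss_and_grads(x, y, rng=np.random.default_rng(7))
        assert l1 == l2
        for key in g1:
            np.testing.assert_array_equal(g1[key], g2[key])


class TestTraining:
    def _toy_batches(self, n=32, seed=0):
        """Linearly separable toy task: class-0 windows carry a large
        constant offset on channel 0."""
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 2, 40)).astype(np.float32)
        labels = np.zeros((n, 6), dtype=np.int8)
        labels[: n // 2, 0] = 1
        data[: n // 2, 0, :] += 3.0
        return make_batch(data[: n - 8], labels[: n - 8]), make_batch(
            data[n - 8 :], labels[n - 8 :]
        )

    def test_zero_learning_rate_keeps_weights(self):
        tr, va = self._toy_batches()
        net = build_model(tiny_spec())
        before = {k: v.copy() for k, v in net.params.items()}
        train(net, tr, va, TrainConfig(learning_rate=0.0, batch_size=8))
        for key, val in before.items():
            np.testing.assert_array_equal(net.params[key], val)

    def test_loss_decreases_on_separable_fixture(self):
        tr, va = self._toy_batches(n=64)
        net = build_model(tiny_spec(seed=3))
        cfg = TrainConfig(batch_size=8, learning_rate=3e-3, checkpoint_every=1)
        trained = train(net, tr, va, cfg)
        losses = [h["val_loss"] for h in trained.history]
        assert losses[-1] < losses[0]

    def test_best_loss_state_attains_history_minimum(self):
        tr, va = self._toy_batches(n=64)
        trained = train(
            build_model(tiny_spec(seed=4)),
            tr,
            va,
            TrainConfig(batch_size=8, learning_rate=3e-3, checkpoint_every=2),
        )
        assert trained.best_loss_state is not None
        assert trained.best_acc_state is not None
        # reload the snapshot and re-evaluate: must equal the recorded min
        probs = predict(trained, va, "best_loss")
        y = va.labels.astype(float)
        p = np.clip(probs, 1e-7, 1 - 1e-7)
        loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
        assert loss == pytest.approx(trained.best_val_loss, abs=1e-6)

    def test_epochs_default_single(self):
        assert TrainConfig().epochs == 1

    def test_empty_batch_rejected(self):
        tr, va = self._toy_batches()
        empty = make_batch(
            np.zeros((0, 2, 40), dtype=np.float32), np.zeros((0, 6), dtype=np.int8)
        )
        with pytest.raises(SizingError):
            train(build_model(tiny_spec()), empty, va)

    def test_training_deterministic_given_seeds(self):
        tr, va = self._toy_batches(n=48)
        cfg = TrainConfig(batch_size=8, learning_rate=1e-3, checkpoint_every=3)
        a = train(build_model(tiny_spec(seed=5)), tr, va, cfg)
        b = train(build_model(tiny_spec(seed=5)), tr, va, cfg)
        assert a.history == b.history
        for key in a.model.params:
            np.testing.assert_array_equal(a.model.params[key], b.model.params[key])


class TestPredict:
    def test_repeated_calls_identical(self):
        rng = np.random.default_rng(0)
        tr_data = rng.standard_normal((24, 2, 40)).astype(np.float32)
        labels = (rng.random((24, 6)) < 0.3).astype(np.int8)
        tr = make_batch(tr_data[:16], labels[:16])
        va = make_batch(tr_data[16:], labels[16:])
        trained = train(
            build_model(tiny_spec(dropout=0.2)),
            tr,
            va,
            TrainConfig(batch_size=8, checkpoint_every=1),
        )
        p1 = predict(trained, va, "best_loss")
        p2 = predict(trained, va, "best_loss")
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_separable_fixture_reaches_perfect_auc(self):
        """End-to-end: training on a separable task yields AUC 1.0 for the
        informative class."""
        from eegnda.metrics import roc_auc

        rng = np.random.default_rng(1)
        n = 96
        data = rng.standard_normal((n, 2, 40)).astype(np.float32)
        labels = np.zeros((n, 6), dtype=np.int8)
        labels[: n // 2, 0] = 1
        data[: n // 2, 0, :] += 4.0
        perm = rng.permutation(n)
        data, labels = data[perm], labels[perm]
        tr = make_batch(data[:64], labels[:64])
        va = make_batch(data[64:80], labels[64:80])
        te = make_batch(data[80:], labels[80:])
        trained = train(
            build_model(tiny_spec(seed=2)),
            tr,
            va,
            TrainConfig(
                epochs=6, batch_size=8, learning_rate=1e-2, checkpoint_every=4
            ),
        )
        scores = predict(trained, te, "best_loss")
        assert roc_auc(te.labels[:, 0], scores[:, 0]) == 1.0

    def test_shape_mismatch_rejected(self):
        tr_data = np.zeros((8, 2, 40), dtype=np.float32)
        labels = np.zeros((8, 6), dtype=np.int8)
        labels[::2, 0] = 1
        tr = make_batch(tr_data, labels)
        trained = train(
            build_model(tiny_spec()), tr, tr, TrainConfig(batch_size=4)
        )
        bad = make_batch(np.zeros((2, 2, 39), dtype=np.float32), labels[:2])
        with pytest.raises(SizingError):
            predict(trained, bad)
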
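import numpy as np
import pytest

from rpaf import _nn
from rpaf.ecg import ParameterError
from rpaf.model import (ModelConfig, TrainConfig, build_model, crossvalidate,
                        load_model, predict, save_model, train)

TINY = ModelConfig(input_size=16, stem_channels=4, block_channels=(4, 6, 8),
                   fc_width=8)


def _blobs(n_per_class, size, rng, scale=1.0):
    """Separable image classes: noise vs noise + diagonal ridge."""
    x = rng.normal(0.0, 0.1, size=(2 * n_per_class, size, size))
    x[n_per_class:] += np.eye(size) * scale
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    perm = rng.permutation(2 * n_per_class)
    return x[perm], y[perm]


class TestBuild:
    def test_forward_shape_and_softmax(self, rng):
        model = build_model(TINY, seed=0)
        logits = model.forward(rng.normal(size=(3, 16, 16)))
        assert logits.shape == (3, 2)
        p = _nn.softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_seed_invariant(self):
        a, b = build_model(TINY, seed=0), build_model(TINY, seed=99)
        assert a.n_parameters() == b.n_parameters()
        assert "params" in a.summary()

    def test_default_model_within_size_bound(self):
        # the reference design keeps the checkpoint comfortably below ~11 MB
        n = build_model(ModelConfig(input_size=64)).n_parameters()
        assert n * 4 / 2**20 <= 11.0

    def test_raw1d_variant(self, rng):
        cfg = ModelConfig(variant="raw1d", input_size=500, stem_channels=4,
                          block_channels=(4, 6, 8), fc_width=8)
        model = build_model(cfg, seed=0)
        assert model.forward(rng.normal(size=(2, 500))).shape == (2, 2)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ParameterError):
            build_model(TINY).forward(rng.normal(size=(2, 20, 20)))

    def test_residual_identity_mapping(self, rng):
        """Zero convolutions + pass-through normalisation give y = x (x >= 0)."""
        block = _nn.ResidualBlock(4, 4, (3, 3), stride=1,
                                  rng=np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.params["w"][:] = 0.0
            conv.params["b"][:] = 0.0
        x = np.abs(rng.normal(size=(2, 4, 8, 8)))
        out = block.forward(x, training=False)  # running stats are (0, 1)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_gradient_reaches_stem(self, rng):
        """Skip connections keep gradients alive through all three blocks."""
        model = build_model(TINY, seed=1)
        x = rng.normal(size=(4, 16, 16))
        logits = model.forward(x, training=True)
        _, grad = _nn.cross_entropy_grad(logits, np.array([0, 1, 0, 1]))
        model.backward(grad)
        stem_conv = model.stem.layers[0]
        assert np.abs(stem_conv.grads["w"]).max() > 0


class TestPredict:
    def test_probabilities_valid_and_order_preserved(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.normal(size=(6, 16, 16))
        p = predict(model, x)
        assert np.all((0 <= p) & (p <= 1))
        x2 = np.concatenate([x, x[:2]])
        p2 = predict(model, x2)
        np.testing.assert_allclose(p2[:6], p, atol=1e-12)
        np.testing.assert_allclose(p2[6:], p[:2], atol=1e-12)

    def test_untrained_not_saturated(self, rng):
        """Mean class-1 probability of a fresh model stays near chance."""
        x = rng.normal(size=(20, 16, 16))
        means = [predict(build_model(TINY, seed=s), x).mean() for s in range(10)]
        assert all(0.2 <= m <= 0.8 for m in means)


class TestTrain:
    def test_learns_separable_problem(self, rng):
        x, y = _blobs(40, 16, rng, scale=2.0)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(lr=3e-3, max_epochs=25, patience=25, seed=0)
        train(model, x[:60], y[:60], x[60:], y[60:], cfg)
        assert max(model.history["val_acc"]) >= 0.9

    def test_initial_loss_near_ln2(self, rng):
        x, y = _blobs(16, 16, rng)
        model = build_model(TINY, seed=3)
        logits = model.forward(x, training=True)
        loss, _ = _nn.cross_entropy_grad(logits, y)
        assert loss == pytest.approx(np.log(2), abs=0.2)

    def test_early_stopping_halts(self, rng):
        """Rising validation loss stops training before max_epochs."""
        x, y = _blobs(10, 16, rng)
        xv = rng.normal(size=(8, 16, 16))  # validation unrelated to training
        yv = np.array([0, 1] * 4)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(lr=5e-2, max_epochs=50, patience=1, seed=0)
        train(model, x, y, xv, yv, cfg)
        assert len(model.history["val_loss"]) < 50

    def test_history_and_determinism(self, rng):
        x, y = _blobs(12, 16, rng)
        cfg = TrainConfig(lr=1e-3, max_epochs=3, patience=3, seed=7)
        h = []
        for _ in range(2):
            model = build_model(TINY, seed=7)
            train(model, x[:16], y[:16], x[16:], y[16:], cfg)
            h.append(model.history)
        assert h[0]["train_loss"] == h[1]["train_loss"]
        assert len(h[0]["train_loss"]) == len(h[0]["val_acc"]) == 3

    def test_single_class_rejected(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.normal(size=(4, 16, 16))
        with pytest.raises(ParameterError):
            train(model, x, np.zeros(4, int), x, np.zeros(4, int))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_model(TINY, seed=0)
        model.history = {"val_loss": [0.5, 0.4]}
        x = rng.normal(size=(3, 16, 16))
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(predict(back, x), predict(model, x), atol=1e-12)
        assert back.history["val_loss"] == [0.5, 0.4]
        assert back.config == model.config


class TestCrossValidate:
    def test_partition_and_aggregate(self, rng):
        x, y = _blobs(15, 16, rng)
        cfg = TrainConfig(lr=1e-3, max_epochs=2, patience=2, seed=0, folds=5)
        folds, summary = crossvalidate(x, y, TINY, cfg)
        assert len(folds) == 5
        accs = [m.accuracy for m in folds]
        assert summary["accuracy"][0] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_record_disjoint_folds(self, rng):
        x, y = _blobs(15, 16, rng)
        groups = np.arange(30) // 3  # 10 records of 3 segments
        cfg = TrainConfig(lr=1e-3, max_epochs=1, patience=1, seed=0, folds=5)
        folds, _ = crossvalidate(x, y, TINY, cfg, groups=groups)
        assert len(folds) == 5

    def test_infeasible(self, rng):
        x, y = _blobs(2, 16, rng)
        with pytest.raises(ParameterError):
            crossvalidate(x, y, TINY, TrainConfig(lr=1e-3, folds=5))
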
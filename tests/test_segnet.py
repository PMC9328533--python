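import numpy as np
import pytest

from svimon.errors import ParameterError, ShapeError
from svimon.scenegen import SceneParams, generate_scene
from svimon.segnet import (
    SegModel,
    TrainConfig,
    UNetSpec,
    build_fcn,
    build_unet,
    load_model,
    predict_mask,
    save_model,
    train_model,
)
from svimon.segnet.nn import softmax_cross_entropy

TINY = UNetSpec(depth=2, base_filters=4, n_classes=3, dropout_rate=0.0)


class TestBuildUnet:
    def test_output_shape_and_normalization(self, rng):
        model = build_unet(UNetSpec(depth=4, base_filters=4, dropout_rate=0.0), seed=0)
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (1, 3, 64, 64)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-5

    def test_encoder_decoder_mirror_sizes(self, rng):
        model = build_unet(UNetSpec(depth=4, base_filters=2, dropout_rate=0.0), seed=0)
        sizes = []
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        # walk the encoder manually to observe feature-map sizes
        h = x
        for lvl in range(4):
            for layer in model.enc[lvl]:
                h = layer.forward(h)
            sizes.append(h.shape[2])
            h = model.pools[lvl].forward(h)
        assert sizes == [64, 32, 16, 8]
        assert h.shape[2] == 4  # bottleneck resolution
        # the decoder restores them in mirrored order by construction
        logits = model.forward(x)
        assert logits.shape[2:] == (64, 64)

    def test_indivisible_input_raises(self, rng):
        model = build_unet(UNetSpec(depth=4, base_filters=2), seed=0)
        with pytest.raises(ShapeError):
            model.forward(rng.random((1, 3, 60, 60)).astype(np.float32))

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            UNetSpec(depth=0)
        with pytest.raises(ParameterError):
            UNetSpec(dropout_rate=1.0)

    def test_normalization_random_weights_property(self, rng):
        for seed in range(3):
            model = build_unet(TINY, seed=seed)
            x = rng.random((2, 3, 16, 16)).astype(np.float32)
            probs = model.predict_proba(x)
            assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-5

    def test_fcn_has_no_skips(self):
        fcn = build_fcn(TINY, seed=0)
        unet = build_unet(TINY, seed=0)
        assert not fcn.skips and unet.skips
        # skip-free decoder convs consume half the channels
        assert fcn.dec[0]["convs"][0].w.shape[1] * 2 == unet.dec[0]["convs"][0].w.shape[1]


class TestPredictMask:
    def test_uniform_logits_tie_break_to_class_0(self):
        model = build_unet(TINY, seed=0)
        for p, _ in model.params():
            p[...] = 0.0  # all-zero weights -> identical logits everywhere
        mask, probs = predict_mask(model, np.zeros((16, 16, 3), dtype=np.uint8))
        assert (mask == 0).all()
        assert np.allclose(probs, 1.0 / 3.0, atol=1e-6)

    def test_predicted_ids_in_range(self, rng, tiny_scene):
        model = build_unet(TINY, seed=1)
        mask, _ = predict_mask(model, tiny_scene.image)
        assert set(np.unique(mask)) <= {0, 1, 2}
        assert mask.shape == tiny_scene.mask.shape

    def test_shape_mismatch(self, rng):
        model = build_unet(TINY, seed=0)
        with pytest.raises(ShapeError):
            predict_mask(model, rng.random((15, 15, 3)))


class TestGradients:
    def test_directional_derivative(self, rng):
        model = build_unet(TINY, seed=1)
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        y = rng.integers(0, 3, size=(2, 8, 8))
        model.zero_grad()
        _, dl, _ = softmax_cross_entropy(model.forward(x, train=True), y)
        model.backward(dl)
        params = model.params()
        # probe along the gradient itself: maximal signal over float32 noise
        dirs = [g.copy() for _, g in params]
        analytic = sum(float((g * d).sum()) for (_, g), d in zip(params, dirs))
        eps = 1e-2
        for (p, _), d in zip(params, dirs):
            p += eps * d
        l1, _, _ = softmax_cross_entropy(model.forward(x), y)
        for (p, _), d in zip(params, dirs):
            p -= 2 * eps * d
        l2, _, _ = softmax_cross_entropy(model.forward(x), y)
        numeric = (l1 - l2) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.05)


def _mini_dataset(n, seed=0, side=32):
    return [
        generate_scene(
            SceneParams(height=side, width=side, veg_fraction=0.2 + 0.03 * (i % 5), seed=seed + i)
        )
        for i in range(n)
    ]


class TestTrainModel:
    def test_loss_decreases(self):
        pairs = _mini_dataset(20)
        model = build_unet(UNetSpec(depth=2, base_filters=8, dropout_rate=0.0), seed=0)
        cfg = TrainConfig(batch_size=8, learning_rate=0.01, max_epochs=5, early_stop_patience=4, seed=0)
        model, hist = train_model(model, pairs[:16], pairs[16:], cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_history_lengths_match_stopped_epoch(self):
        pairs = _mini_dataset(12)
        model = build_unet(TINY, seed=0)
        cfg = TrainConfig(batch_size=4, learning_rate=0.005, max_epochs=3, early_stop_patience=2, seed=0)
        _, hist = train_model(model, pairs[:8], pairs[8:], cfg)
        for arr in (hist.train_loss, hist.val_loss, hist.train_acc, hist.val_acc):
            assert len(arr) == hist.stopped_epoch

    def test_early_stopping_triggers(self):
        # learning rate ~0 -> validation loss never improves -> stop at patience+1
        pairs = _mini_dataset(10)
        model = build_unet(TINY, seed=0)
        cfg = TrainConfig(
            batch_size=4, learning_rate=1e-12, max_epochs=50, early_stop_patience=2, seed=0
        )
        _, hist = train_model(model, pairs[:8], pairs[8:], cfg)
        assert hist.stopped_epoch < 50
        assert hist.stopped_epoch <= 1 + cfg.early_stop_patience

    def test_empty_sets_rejected(self):
        model = build_unet(TINY, seed=0)
        with pytest.raises(ParameterError):
            train_model(model, [], [], TrainConfig())

    def test_dropout_regime_no_nan(self):
        # validation accuracy may exceed training accuracy when dropout is
        # active only in training; assert the run is finite, not the inequality
        pairs = _mini_dataset(12)
        model = build_unet(UNetSpec(depth=2, base_filters=4, dropout_rate=0.5), seed=0)
        cfg = TrainConfig(batch_size=4, learning_rate=0.01, max_epochs=3, early_stop_patience=2, seed=0)
        _, hist = train_model(model, pairs[:8], pairs[8:], cfg)
        assert np.isfinite(hist.train_loss).all()
        assert np.isfinite(hist.val_loss).all()

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            TrainConfig(batch_size=0)
        with pytest.raises(ParameterError):
            TrainConfig(early_stop_patience=300, max_epochs=200)

    def test_overfit_single_scene(self):
        # saturation run: a model trained on one constant scene reproduces it
        pair = generate_scene(SceneParams(height=32, width=32, veg_fraction=0.3, seed=5))
        model = build_unet(UNetSpec(depth=2, base_filters=8, dropout_rate=0.0), seed=0)
        cfg = TrainConfig(
            batch_size=1, learning_rate=0.02, momentum=0.9, clip_norm=2.0,
            max_epochs=60, early_stop_patience=59, seed=0,
        )
        model, _ = train_model(model, [pair] * 4, [pair], cfg)
        pred, _ = predict_mask(model, pair.image)
        assert (pred == pair.mask).mean() >= 0.99


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_scene):
        model = build_unet(TINY, seed=3)
        path = save_model(model, tmp_path / "model.npz")
        back = load_model(path)
        a, _ = predict_mask(model, tiny_scene.image)
        b, _ = predict_mask(back, tiny_scene.image)
        assert np.array_equal(a, b)
        assert back.spec == model.spec
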
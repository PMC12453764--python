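"""Network core: layer semantics, residual identity, softmax laws, batch-norm
modes, gradient correctness, and training behaviour on toy data."""

import numpy as np
import pytest

from dermapatch import nn
from dermapatch.fcrn import (
    FcrnSpec, FcrnTrainConfig, FcrnModel, build_fcrn, fcrn_forward, train_fcrn,
    save_checkpoint, load_checkpoint,
)
from _oracles import conv2d_reference, grad_check


SMALL_SPEC = FcrnSpec(conv1_filters=8, block_filters=8, conv2_filters=16)


class TestLayers:
    def test_conv2d_matches_direct_summation(self, rng):
        layer = nn.Conv2D(3, 4, 3, rng, np.float64)
        x = rng.random((2, 6, 6, 3))
        out = layer.forward(x)
        ref = conv2d_reference(x, layer.W.value, layer.b.value)
        assert np.abs(out - ref).max() < 1e-12

    def test_residual_zero_weights_is_identity_for_nonneg(self, rng):
        block = nn.Residual([
            nn.Conv2D(4, 4, 3, rng, np.float64), nn.BatchNorm(4, dtype=np.float64),
            nn.ReLU(),
            nn.Conv2D(4, 4, 3, rng, np.float64), nn.BatchNorm(4, dtype=np.float64),
        ])
        for layer in block.inner:
            if isinstance(layer, nn.Conv2D):
                layer.W.value[...] = 0.0
                layer.b.value[...] = 0.0
        x = rng.random((2, 5, 5, 4))  # non-negative
        assert np.allclose(block.forward(x), x, atol=1e-12)

    def test_residual_zero_input_gives_zero(self, rng):
        block = nn.Residual([
            nn.Conv2D(4, 4, 3, rng, np.float64), nn.BatchNorm(4, dtype=np.float64),
            nn.ReLU(),
            nn.Conv2D(4, 4, 3, rng, np.float64), nn.BatchNorm(4, dtype=np.float64),
        ])
        for layer in block.inner:
            if isinstance(layer, nn.Conv2D):
                layer.b.value[...] = 0.0
        x = np.zeros((1, 4, 4, 4))
        assert np.allclose(block.forward(x), 0.0, atol=1e-9)

    def test_residual_with_bn_inference_matches_reference(self, rng):
        """Random small weights, BN in inference mode, against a hand-rolled
        convolution + normalisation + skip reference."""
        conv1 = nn.Conv2D(8, 8, 3, rng, np.float64)
        bn1 = nn.BatchNorm(8, dtype=np.float64)
        conv2 = nn.Conv2D(8, 8, 3, rng, np.float64)
        bn2 = nn.BatchNorm(8, dtype=np.float64)
        for bn in (bn1, bn2):
            bn.running_mean = rng.normal(size=8) * 0.1
            bn.running_var = rng.random(8) + 0.5
            bn.gamma.value[...] = rng.random(8) + 0.5
            bn.beta.value[...] = rng.normal(size=8) * 0.1
        block = nn.Residual([conv1, bn1, nn.ReLU(), conv2, bn2])
        x = rng.random((1, 4, 4, 8)) * 0.1

        def bn_ref(z, bn):
            return (bn.gamma.value * (z - bn.running_mean)
                    / np.sqrt(bn.running_var + bn.eps) + bn.beta.value)

        h = bn_ref(conv2d_reference(x, conv1.W.value, conv1.b.value), bn1)
        h = np.maximum(h, 0.0)
        h = bn_ref(conv2d_reference(h, conv2.W.value, conv2.b.value), bn2)
        ref = np.maximum(h + x, 0.0)
        assert np.abs(block.forward(x) - ref).max() < 1e-5

    def test_maxpool_halves_and_routes_gradient(self, rng):
        pool = nn.MaxPool2D()
        x = rng.random((1, 4, 4, 1))
        out = pool.forward(x)
        assert out.shape == (1, 2, 2, 1)
        assert out[0, 0, 0, 0] == x[0, :2, :2, 0].max()
        g = pool.backward(np.ones_like(out))
        assert g.sum() == 4.0  # one winner per window

    def test_batchnorm_training_vs_inference(self, rng):
        bn = nn.BatchNorm(3, dtype=np.float64)
        x = rng.normal(2.0, 3.0, size=(64, 3))
        out = bn.forward(x, training=True)
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert np.abs(out.std(axis=0) - 1).max() < 1e-3
        # first training batch seeds the running moments
        assert np.allclose(bn.running_mean, x.mean(axis=0))
        out_inf = bn.forward(x, training=False)
        assert np.allclose(out_inf, out, atol=1e-6)


class TestSoftmax:
    def test_symmetric_logits_give_half(self):
        assert np.allclose(nn.softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])

    def test_closed_form_ln2(self):
        p = nn.softmax(np.array([[np.log(2.0), 0.0]]))
        assert np.allclose(p, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_normalisation_and_shift_invariance(self, rng):
        z = rng.normal(size=(10, 2))
        p = nn.softmax(z)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6
        assert np.abs(nn.softmax(z + 7.3) - p).max() < 1e-9

    def test_weighted_loss_reduces_to_unweighted(self, rng):
        z = rng.normal(size=(6, 2))
        y = np.array([0, 1, 0, 1, 1, 0])
        l0, _, d0 = nn.softmax_cross_entropy(z, y)
        l1, _, d1 = nn.softmax_cross_entropy(z, y, np.array([1.0, 1.0]))
        assert l0 == pytest.approx(l1)
        assert np.allclose(d0, d1)


class TestFcrnModel:
    def test_forward_probabilities_sum_to_one(self, rng):
        model = build_fcrn(SMALL_SPEC, seed=0, dtype="float64")
        pred = fcrn_forward(rng.random((32, 32, 3)), model)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(pred.logits) == np.argmax(pred.probabilities)

    def test_fully_convolutional_accepts_larger_inputs(self, rng):
        model = build_fcrn(SMALL_SPEC, seed=0, dtype="float64")
        out = model.logits(rng.random((1, 48, 56, 3)))
        assert out.shape == (1, 2)
        with pytest.raises(ValueError):
            model.logits(rng.random((1, 16, 16, 3)))

    def test_gradient_agreement(self, rng):
        """Numerical vs analytic gradients on a 3-patch batch."""
        model = build_fcrn(SMALL_SPEC, seed=3, dtype="float64")
        x = rng.random((3, 32, 32, 3))
        y = np.array([0, 1, 1])
        grad_check(model, x, y, tol=1e-4)

    def test_epochs_zero_returns_initialization(self, rng):
        x = rng.random((8, 32, 32, 3))
        y = np.array([0, 1] * 4)
        model, hist = train_fcrn(x, y, SMALL_SPEC,
                                 FcrnTrainConfig(epochs=0, seed=4, dtype="float64"))
        ref = build_fcrn(SMALL_SPEC, seed=4, dtype="float64")
        for a, b in zip(nn.get_state(model.net), nn.get_state(ref.net)):
            assert np.array_equal(a, b)
        assert hist["train_loss"] == []

    def test_single_class_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            train_fcrn(rng.random((6, 32, 32, 3)), np.zeros(6, dtype=int), SMALL_SPEC)
        with pytest.raises(ValueError):
            train_fcrn(np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int), SMALL_SPEC)

    def test_loss_decreases_on_toy_set_across_seeds(self, rng):
        """Training loss after 10 epochs is below the first epoch's loss for
        three seeds, on a 50-patch separable toy set."""
        x = rng.random((50, 32, 32, 3)) * 0.2
        y = np.array([0, 1] * 25)
        x[y == 1] += 0.5
        for seed in (0, 1, 2):
            _, hist = train_fcrn(
                x, y, SMALL_SPEC,
                FcrnTrainConfig(epochs=10, seed=seed, patience=50, dtype="float64"))
            assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_seeded_training_is_reproducible(self, rng):
        x = rng.random((20, 32, 32, 3))
        y = np.array([0, 1] * 10)
        cfg = FcrnTrainConfig(epochs=2, seed=9, dtype="float64")
        m1, h1 = train_fcrn(x, y, SMALL_SPEC, cfg)
        m2, h2 = train_fcrn(x, y, SMALL_SPEC, cfg)
        assert h1 == h2
        for a, b in zip(nn.get_state(m1.net), nn.get_state(m2.net)):
            assert np.array_equal(a, b)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        x = rng.random((12, 32, 32, 3))
        y = np.array([0, 1] * 6)
        model, hist = train_fcrn(x, y, SMALL_SPEC,
                                 FcrnTrainConfig(epochs=1, seed=2, dtype="float64"))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, hist, path)
        back, hist2 = load_checkpoint(path)
        assert hist2["train_loss"] == hist["train_loss"]
        probe = rng.random((2, 32, 32, 3))
        assert np.allclose(back.predict_proba(probe), model.predict_proba(probe),
                           atol=1e-7)
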
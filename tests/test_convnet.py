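"""Multiscale convolutional readout: operators, training, evaluation."""

import math

import numpy as np
import pytest

from soconvesn.convnet import (
    BLOCKS,
    ConvEsnReadout,
    EsrDataset,
    ModelConfig,
    TrainConfig,
    conv_dual,
    conv_single,
    max_over_time,
    softmax,
    stack_esr_samples,
)

from conftest import naive_conv_dual, naive_conv_single


class TestConvSingle:
    def test_zero_filter_zero_map(self):
        out = conv_single(np.random.default_rng(0).normal(size=(6, 3)), np.zeros((2, 3)), 0.0)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_k1_identity_with_relu(self):
        esr = np.array([[0.1], [-0.2], [0.3]])
        out = conv_single(esr, np.array([[1.0]]), 0.0)
        np.testing.assert_allclose(out, [0.1, 0.0, 0.3])

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            T, N, k = int(rng.integers(3, 10)), int(rng.integers(1, 5)), int(rng.integers(1, 3))
            esr = rng.normal(size=(T, N))
            filt = rng.normal(size=(k, N))
            bias = float(rng.normal())
            got = conv_single(esr, filt, bias)
            want = naive_conv_single(esr, filt, bias)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_filter_longer_than_sequence(self):
        with pytest.raises(ValueError, match="k=5"):
            conv_single(np.ones((3, 2)), np.ones((5, 2)))


class TestConvDual:
    def test_zero_right_subfilter_decouples(self):
        rng = np.random.default_rng(1)
        esr_l, esr_r = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        filt = np.zeros((2, 3, 2))
        filt[:, :, 0] = rng.normal(size=(2, 3))
        out = conv_dual(esr_l, esr_r, filt, 0.3)
        np.testing.assert_allclose(out, conv_single(esr_l, filt[:, :, 0], 0.3), atol=1e-12)

    def test_equal_channels_double_response(self):
        rng = np.random.default_rng(2)
        esr = rng.normal(size=(5, 2))
        sub = rng.normal(size=(2, 2))
        filt = np.stack([sub, sub], axis=2)
        # ReLU commutes with positive scaling, so relu(2a) = 2 relu(a)
        np.testing.assert_allclose(
            conv_dual(esr, esr, filt, 0.0), 2 * conv_single(esr, sub, 0.0), atol=1e-12
        )

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            T, N, k = int(rng.integers(3, 9)), int(rng.integers(1, 4)), int(rng.integers(1, 3))
            esr_l, esr_r = rng.normal(size=(T, N)), rng.normal(size=(T, N))
            filt = rng.normal(size=(k, N, 2))
            bias = float(rng.normal())
            np.testing.assert_allclose(
                conv_dual(esr_l, esr_r, filt, bias),
                naive_conv_dual(esr_l, esr_r, filt, bias),
                atol=1e-9,
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shape"):
            conv_dual(np.ones((4, 2)), np.ones((5, 2)), np.ones((2, 2, 2)))


class TestMaxOverTime:
    def test_basic(self):
        assert max_over_time(np.array([1.0, 3.0, 2.0])) == 3.0

    def test_constant(self):
        assert max_over_time(np.full(5, 0.7)) == 0.7

    def test_translation_invariance_of_shifted_motif(self):
        motif = np.array([0.2, 0.9, 0.4])
        for shift in range(6):
            m = np.zeros(8)
            m[shift : shift + 3] = motif
            assert max_over_time(m) == 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            max_over_time(np.array([]))


def _toy_dataset(rng, n=16, T=8, N=3, classes=("a", "b")):
    """Linearly separable two-class block data: class b runs hotter."""
    samples, labels = [], []
    for i in range(n):
        label = classes[i % 2]
        offset = 0.5 if label == "b" else -0.5
        esrs = {p: np.tanh(rng.normal(offset, 0.3, size=(T, N))) for p in BLOCKS["ARMS"] + BLOCKS["LEGS"] + BLOCKS["CT"]}
        samples.append(esrs)
        labels.append(label)
    return stack_esr_samples(samples, labels, classes=list(classes))


class TestForward:
    def test_zero_weights_uniform_probabilities(self):
        cfg = ModelConfig(reservoir_size=3, num_classes=4, scales=(2,), filters_per_scale=2)
        model = ConvEsnReadout(cfg, seed=0)
        for key in model.params:
            model.params[key] = np.zeros_like(model.params[key])
        esrs = {p: np.random.default_rng(0).normal(size=(6, 3)) for p in ("LA", "RA", "CT", "LL", "RL")}
        res = model.forward(esrs)
        np.testing.assert_allclose(res.probabilities, 0.25)

    def test_probabilities_normalized(self):
        cfg = ModelConfig(reservoir_size=4, num_classes=3)
        model = ConvEsnReadout(cfg, seed=1)
        esrs = {p: np.random.default_rng(2).normal(size=(10, 4)) for p in ("LA", "RA", "CT", "LL", "RL")}
        res = model.forward(esrs)
        assert abs(res.probabilities.sum() - 1.0) < 1e-6
        assert np.all(res.probabilities >= 0)
        assert res.predicted == int(res.probabilities.argmax())

    def test_hand_computed_two_class_toy(self):
        # T=3, N=2, one scale k=2, one filter per block, all weights set by
        # hand; the expected probability is computed step by step below
        cfg = ModelConfig(reservoir_size=2, num_classes=2, scales=(2,), filters_per_scale=1)
        model = ConvEsnReadout(cfg, seed=0)
        esr = np.array([[0.1, 0.2], [0.3, -0.1], [0.0, 0.4]])
        esrs = {p: esr for p in ("LA", "RA", "CT", "LL", "RL")}
        # CT filter: ones over a 2x2 window; dual blocks: ones over 2x4
        model.params["W_CT_2"] = np.ones((1, 4))
        model.params["b_CT_2"] = np.array([0.1])
        model.params["W_ARMS_2"] = np.ones((1, 8))
        model.params["b_ARMS_2"] = np.array([0.0])
        model.params["W_LEGS_2"] = np.ones((1, 8))
        model.params["b_LEGS_2"] = np.array([0.0])
        model.params["W_fc"] = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        model.params["b_fc"] = np.array([0.0, 0.2])
        # windows sums: rows 0-1 -> 0.5, rows 1-2 -> 0.6
        ct_pool = 0.6 + 0.1  # max(relu(0.5+0.1), relu(0.6+0.1))
        dual_pool = 1.2  # both channels identical: 2 * 0.6
        logits = np.array([ct_pool, dual_pool + dual_pool + 0.2])
        expected = np.exp(logits) / np.exp(logits).sum()
        res = model.forward(esrs)
        np.testing.assert_allclose(res.probabilities, expected, atol=1e-9)


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self):
        rng = np.random.default_rng(3)
        ds = _toy_dataset(rng)
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2,), filters_per_scale=2)
        model = ConvEsnReadout(cfg, seed=5)
        before = {k: v.copy() for k, v in model.params.items()}
        acc0 = model.evaluate(ds).accuracy
        model.fit(ds, ds, TrainConfig(learning_rate=0.0, epochs=1, seed=0))
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        assert model.evaluate(ds).accuracy == acc0

    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(4)
        ds = _toy_dataset(rng, n=24)
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2, 3), filters_per_scale=4)
        model = ConvEsnReadout(cfg, seed=2)
        hist = model.fit(ds, ds, TrainConfig(learning_rate=0.01, epochs=30, seed=1))
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert model.evaluate(ds).accuracy > 0.9

    def test_seeded_training_is_reproducible(self):
        rng = np.random.default_rng(5)
        ds = _toy_dataset(rng)
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2,), filters_per_scale=2)
        tc = TrainConfig(learning_rate=0.005, epochs=5, seed=9)
        m1, m2 = ConvEsnReadout(cfg, seed=4), ConvEsnReadout(cfg, seed=4)
        m1.fit(ds, None, tc)
        m2.fit(ds, None, tc)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(6)
        ds = _toy_dataset(rng)
        only_a = EsrDataset(
            blocks={k: v[ds.labels == 0] for k, v in ds.blocks.items()},
            labels=ds.labels[ds.labels == 0],
            classes=ds.classes,
        )
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2,), filters_per_scale=2)
        with pytest.raises(ValueError, match="absent"):
            ConvEsnReadout(cfg, seed=0).fit(only_a, None, TrainConfig(epochs=1))


class TestEvaluate:
    def _dataset_and_model(self):
        rng = np.random.default_rng(7)
        ds = _toy_dataset(rng, n=8)
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2,), filters_per_scale=2)
        return ds, ConvEsnReadout(cfg, seed=0)

    def test_accuracy_is_trace_over_total(self):
        ds, model = self._dataset_and_model()
        rep = model.evaluate(ds)
        assert rep.accuracy == np.trace(rep.confusion) / rep.confusion.sum()
        assert rep.confusion.sum(axis=1).tolist() == [4, 4]

    def test_three_of_four_correct(self):
        # craft predictions by evaluating a model trained to perfection,
        # then flipping one label in the dataset
        rng = np.random.default_rng(8)
        ds = _toy_dataset(rng, n=16)
        cfg = ModelConfig(reservoir_size=3, num_classes=2, scales=(2,), filters_per_scale=4)
        model = ConvEsnReadout(cfg, seed=1)
        model.fit(ds, None, TrainConfig(learning_rate=0.01, epochs=40, seed=0))
        assert model.evaluate(ds).accuracy == 1.0
        flipped = EsrDataset(blocks=ds.blocks, labels=ds.labels.copy(), classes=ds.classes)
        flipped.labels[:4] = 1 - flipped.labels[:4]
        assert model.evaluate(flipped).accuracy == 0.75

    def test_empty_dataset_rejected(self):
        ds, model = self._dataset_and_model()
        empty = EsrDataset(
            blocks={k: v[:0] for k, v in ds.blocks.items()},
            labels=ds.labels[:0],
            classes=ds.classes,
        )
        with pytest.raises(ValueError, match="empty"):
            model.evaluate(empty)


def test_softmax_of_zeros_is_uniform():
    np.testing.assert_allclose(softmax(np.zeros((2, 5))), 0.2)
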
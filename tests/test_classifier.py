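"""Attention, classification head, losses, and training behaviour."""

import numpy as np
import pytest

from lesionnet.classifier import (AttentionModule, LesionClassifier,
                                  attend, attention_alignment_loss,
                                  build_backbone, classify, confidence_penalty,
                                  cross_entropy, early_stop_epoch,
                                  extract_features, total_loss,
                                  train_classifier)
from lesionnet.classifier.losses import LossBreakdown
from lesionnet.config import ClsTrainConfig
from lesionnet.nn import Tensor


def _zeroed(module):
    for p in module.parameters():
        p.data[...] = 0.0
    return module


class TestBackbone:
    def test_shape_contract_stride8(self):
        bb = build_backbone("tiny", np.random.default_rng(0))
        f = extract_features(np.zeros((64, 64, 3), np.float32), bb)
        assert f.shape == (8, 8, bb.out_channels)

    def test_eval_determinism(self):
        bb = build_backbone("tiny", np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(64, 64, 3)).astype(np.float32)
        np.testing.assert_array_equal(extract_features(x, bb),
                                      extract_features(x, bb))

    def test_zero_input_biasless_gives_zero_features(self):
        bb = build_backbone("tiny", np.random.default_rng(0), bias=False)
        f = extract_features(np.zeros((64, 64, 3), np.float32), bb)
        np.testing.assert_array_equal(f, 0.0)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_backbone("resnet50", np.random.default_rng(0))

    def test_efficientnet_b3_unavailable_at_desk_scale(self):
        with pytest.raises(ValueError, match="efficientnet_b3"):
            build_backbone("efficientnet_b3", np.random.default_rng(0))


class TestAttention:
    def test_zero_parameters_quarter_scaling(self):
        mod = _zeroed(AttentionModule(4, np.random.default_rng(0)))
        f = np.random.default_rng(1).normal(size=(5, 5, 4)).astype(np.float32)
        bundle = attend(f, mod)
        np.testing.assert_allclose(bundle.spatial_map, 0.5, atol=1e-7)
        np.testing.assert_allclose(bundle.channel_weights, 0.5, atol=1e-7)
        np.testing.assert_allclose(bundle.refined_features, 0.25 * f, atol=1e-6)

    def test_gates_strictly_inside_unit_interval(self):
        mod = AttentionModule(8, np.random.default_rng(2))
        f = np.random.default_rng(3).normal(size=(4, 4, 8)).astype(np.float32)
        bundle = attend(f, mod)
        assert 0.0 < bundle.spatial_map.min() <= bundle.spatial_map.max() < 1.0
        assert 0.0 < bundle.channel_weights.min() <= \
            bundle.channel_weights.max() < 1.0

    def test_bias_only_hand_case(self):
        # zero weights, chosen biases: both gates become constants and
        # f_a = f * sigmoid(b_channel) * sigmoid(b_spatial)
        mod = _zeroed(AttentionModule(1, np.random.default_rng(0)))
        mod.fc2.bias.data[...] = 0.7
        mod.spatial_conv.bias.data[...] = -0.3
        f = np.array([[[1.0], [2.0]], [[3.0], [4.0]]], dtype=np.float32)
        bundle = attend(f, mod)
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        np.testing.assert_allclose(bundle.channel_weights, sig(0.7), atol=1e-6)
        np.testing.assert_allclose(bundle.spatial_map, sig(-0.3), atol=1e-6)
        np.testing.assert_allclose(bundle.refined_features,
                                   f * sig(0.7) * sig(-0.3), atol=1e-6)


class TestClassifyHead:
    def _model(self):
        return LesionClassifier(4, np.random.default_rng(0))

    def test_zero_head_uniform_probs(self):
        model = self._model()
        model.proj.weight.data[...] = 0.0
        model.fc.weight.data[...] = 0.0
        model.fc.bias.data[...] = 0.0
        f_a = np.random.default_rng(1).normal(size=(8, 8, 64)).astype(np.float32)
        out = classify(f_a, model)
        np.testing.assert_allclose(out.probs, 0.25, atol=1e-6)

    def test_probs_sum_to_one(self):
        out = classify(np.random.default_rng(2).normal(
            size=(8, 8, 64)).astype(np.float32), self._model())
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-6)
        out.validate()

    def test_logit_shift_invariance(self):
        model = self._model()
        f_a = np.random.default_rng(3).normal(size=(8, 8, 64)).astype(np.float32)
        base = classify(f_a, model).probs
        model.fc.bias.data += 7.5   # constant shift of every logit
        shifted = classify(f_a, model).probs
        np.testing.assert_allclose(base, shifted, atol=1e-5)


class TestLosses:
    def test_cross_entropy_one_hot_zero(self):
        p = np.zeros(7)
        p[3] = 1.0
        assert cross_entropy(p, 3) == pytest.approx(0.0, abs=1e-9)

    def test_cross_entropy_uniform_seven(self):
        assert cross_entropy(np.full(7, 1 / 7), 2) == pytest.approx(
            np.log(7), abs=1e-6)

    def test_cross_entropy_binary_half(self):
        assert cross_entropy(np.array([0.5, 0.5]), 0) == pytest.approx(
            np.log(2), abs=1e-6)

    def test_cross_entropy_label_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.5]), 2)

    def test_alignment_inside_mask_zero(self):
        a = np.zeros((8, 8))
        a[2:4, 2:4] = 1.0
        m = np.zeros((8, 8))
        m[1:5, 1:5] = 1.0
        assert attention_alignment_loss(a, m) == pytest.approx(0.0)

    def test_alignment_outside_mask_one(self):
        a = np.zeros((8, 8))
        a[6:, 6:] = 1.0
        m = np.zeros((8, 8))
        m[:2, :2] = 1.0
        assert attention_alignment_loss(a, m) == pytest.approx(1.0)

    def test_alignment_uniform_quarter_mask(self):
        a = np.ones((8, 8))
        m = np.zeros((8, 8))
        m[:4, :4] = 1.0   # 25% of pixels
        assert attention_alignment_loss(a, m) == pytest.approx(0.75)

    def test_alignment_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8))
        m = (rng.random((8, 8)) > 0.5).astype(float)
        assert attention_alignment_loss(a, m) == pytest.approx(
            attention_alignment_loss(3.7 * a, m), abs=1e-12)

    def test_alignment_zero_mass_warns(self):
        with pytest.warns(UserWarning):
            assert attention_alignment_loss(np.zeros((4, 4)),
                                            np.ones((4, 4))) == 0.0

    def test_total_loss_all_zero_lambdas(self):
        assert total_loss(0.4, 0.3, 0.2, 0.1, (0, 0, 0, 0)).l_total == 0.0

    def test_total_loss_linearity(self):
        lb = total_loss(0.2, 0.3, 0.0, 0.0, (1, 1, 0, 0))
        assert lb.l_total == pytest.approx(0.5)

    def test_total_loss_homogeneity(self):
        a = total_loss(0.2, 0.3, 0.4, 0.5, (1, 2, 3, 4)).l_total
        b = total_loss(0.2, 0.3, 0.4, 0.5, (2, 4, 6, 8)).l_total
        assert b == pytest.approx(2 * a)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(0.1, 0.1, 0.1, 0.1, (1, -1, 1, 1))

    def test_breakdown_identity(self):
        lb = LossBreakdown(0.11, 0.22, 0.33, 0.44, (1.0, 1.0, 0.5, 0.1))
        expected = 0.11 + 0.22 + 0.5 * 0.33 + 0.1 * 0.44
        assert lb.l_total == pytest.approx(expected, abs=1e-6)

    def test_confidence_penalty_range(self):
        assert confidence_penalty(np.full((1, 7), 1 / 7)) == pytest.approx(
            0.0, abs=1e-9)
        onehot = np.zeros((1, 7))
        onehot[0, 0] = 1.0
        assert confidence_penalty(onehot) == pytest.approx(1.0, abs=1e-6)


class TestTraining:
    def test_early_stop_scripted_sequence(self):
        # 1 improving epoch then 25+ flat epochs halts exactly at patience
        metrics = [0.5] + [0.4] * 40
        assert early_stop_epoch(metrics, patience=25) == 26
        assert early_stop_epoch([0.1, 0.2, 0.3], patience=25) == 3

    def test_loss_decreases_on_smoke_run(self, small_samples, trained_segmenter):
        _, hist = train_classifier(
            small_samples[:48], trained_segmenter,
            ClsTrainConfig.desk(epochs=5, patience=5), seed=0)
        assert hist["tr_loss"].iloc[-1] < hist["tr_loss"].iloc[0]

    def test_single_class_rejected(self, small_samples, trained_segmenter):
        only_zero = [s for s in small_samples if s.label == 0]
        with pytest.raises(ValueError):
            train_classifier(only_zero, trained_segmenter,
                             ClsTrainConfig.desk(epochs=1), seed=0)

    def test_attention_loss_column_follows_lambda3(self, small_samples,
                                                   trained_segmenter):
        cfg = ClsTrainConfig.desk(epochs=2, lambdas=(1.0, 1.0, 0.0, 0.1))
        _, hist = train_classifier(small_samples[:36], trained_segmenter,
                                   cfg, seed=1)
        assert "l_att" not in hist.columns

    def test_plain_cnn_ablation_reachable(self, small_samples):
        # no segmentation, no attention: reduces to a standard CNN classifier
        cfg = ClsTrainConfig.desk(epochs=2, use_attention=False,
                                  use_segmentation=False,
                                  lambdas=(0.0, 1.0, 0.0, 0.0))
        pipe, hist = train_classifier(small_samples[:36], None, cfg, seed=2)
        assert pipe.classifier.attention is None
        out = pipe.predict_samples(small_samples[:4])
        assert out.attention_maps is None
        np.testing.assert_array_equal(out.masks, 1.0)

    def test_history_columns(self, small_samples, trained_segmenter):
        _, hist = train_classifier(small_samples[:36], trained_segmenter,
                                   ClsTrainConfig.desk(epochs=2), seed=3)
        for col in ("epoch", "tr_loss", "val_loss", "tr_acc", "val_acc", "lr"):
            assert col in hist.columns
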
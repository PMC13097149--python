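"""MC-dropout moments, rejection analysis, threshold selection, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionnet.classifier import LesionClassifier
from lesionnet.classifier.model import LesionPipeline
from lesionnet.config import ClsTrainConfig
from lesionnet.uncertainty import (MCPrediction, brier_score,
                                   calibration_report, mc_predict,
                                   predictive_moments, rejection_analysis,
                                   select_threshold, tta_predict,
                                   uncertainty_score)


def _make_pred(samples):
    samples = np.asarray(samples, dtype=np.float64)
    mean, var = predictive_moments(samples)
    return MCPrediction(samples=samples, mean=mean, variance=var,
                        T=len(samples)).validate()


class TestMoments:
    def test_identical_rows_zero_variance(self):
        pred = _make_pred([[0.3, 0.7]] * 5)
        np.testing.assert_array_equal(pred.variance, 0.0)

    def test_hand_case_two_rows(self):
        mean, var = predictive_moments(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(mean, [0.5, 0.5])
        np.testing.assert_allclose(var, [0.25, 0.25])   # divide by T

    def test_mean_on_simplex(self):
        rng = np.random.default_rng(0)
        samples = rng.dirichlet(np.ones(5), size=10)
        mean, _ = predictive_moments(samples)
        assert mean.sum() == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(1, 20), st.integers(2, 6), st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_matches_direct_resummation(self, t, c, seed):
        samples = np.random.default_rng(seed).dirichlet(np.ones(c), size=t)
        mean, var = predictive_moments(samples)
        mean_direct = samples.sum(axis=0) / t
        var_direct = ((samples - mean_direct) ** 2).sum(axis=0) / t
        np.testing.assert_allclose(mean, mean_direct, atol=1e-12)
        np.testing.assert_allclose(var, var_direct, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predictive_moments(np.zeros((0, 3)))


class TestMCPredict:
    def test_t1_single_row_zero_variance(self, trained_pipeline, small_samples):
        pred = mc_predict(trained_pipeline, small_samples[0].image, T=1, seed=0)
        assert pred.samples.shape[0] == 1
        np.testing.assert_array_equal(pred.variance, 0.0)

    def test_zero_dropout_rate_no_stochasticity(self, small_samples):
        model = LesionClassifier(3, np.random.default_rng(0), dropout=0.0)
        pipe = LesionPipeline(None, model,
                              ClsTrainConfig.desk(use_segmentation=False,
                                                  dropout=0.0))
        pred = mc_predict(pipe, small_samples[0].image, T=6, seed=1)
        assert np.ptp(pred.samples, axis=0).max() == 0.0
        np.testing.assert_array_equal(pred.variance, 0.0)

    def test_seeded_reproducibility(self, trained_pipeline, small_samples):
        a = mc_predict(trained_pipeline, small_samples[1].image, T=5, seed=7)
        b = mc_predict(trained_pipeline, small_samples[1].image, T=5, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_invalid_t(self, trained_pipeline, small_samples):
        with pytest.raises(ValueError):
            mc_predict(trained_pipeline, small_samples[0].image, T=0, seed=0)


class TestUncertaintyScore:
    def test_zero_variance_class_variance_zero(self):
        pred = _make_pred([[0.2, 0.8]] * 3)
        assert uncertainty_score(pred, "class_variance") == pytest.approx(
            0.0, abs=1e-15)

    def test_entropy_uniform_seven(self):
        pred = _make_pred([np.full(7, 1 / 7)] * 2)
        assert uncertainty_score(pred, "entropy") == pytest.approx(
            np.log(7), abs=1e-6)

    def test_class_variance_hand_case(self):
        pred = _make_pred([[1.0, 0.0], [0.0, 1.0]])
        assert uncertainty_score(pred, "class_variance") == pytest.approx(0.25)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            uncertainty_score(_make_pred([[1.0, 0.0]]), "mutual_information")


class TestTTA:
    def test_flip_symmetric_input_zero_view_variance(self, small_samples):
        model = LesionClassifier(3, np.random.default_rng(0), dropout=0.0)
        pipe = LesionPipeline(None, model,
                              ClsTrainConfig.desk(use_segmentation=False,
                                                  dropout=0.0))
        img = np.random.default_rng(0).random((64, 64, 3)).astype(np.float32)
        img = (img + img[:, ::-1]) / 2
        img = (img + img[::-1]) / 2        # symmetric under both flips
        pred = tta_predict(pipe, img, T=2, seed=0)
        assert np.ptp(pred.samples, axis=0).max() < 1e-6

    def test_zero_dropout_equals_plain_view_average(self, trained_pipeline,
                                                    small_samples):
        img = small_samples[3].image
        model = trained_pipeline.classifier
        old_p = model.drop.p
        model.drop.p = 0.0
        try:
            pred = tta_predict(trained_pipeline, img, T=1, seed=0)
            views = [img, img[:, ::-1], img[::-1], img[::-1, ::-1]]
            expected = np.mean([
                trained_pipeline.predict([np.ascontiguousarray(v)]).probs[0]
                for v in views], axis=0)
            np.testing.assert_allclose(pred.mean, expected, atol=1e-6)
        finally:
            model.drop.p = old_p

    def test_seeded_determinism(self, trained_pipeline, small_samples):
        a = tta_predict(trained_pipeline, small_samples[4].image, T=2, seed=3)
        b = tta_predict(trained_pipeline, small_samples[4].image, T=2, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)


def _brute_force_curve(scores, correct, thresholds):
    rows = []
    scores = np.asarray(scores)
    correct = np.asarray(correct)
    for t in thresholds:
        rej = [s > t for s in scores]
        kept_correct = [c for c, r in zip(correct, rej) if not r]
        n_inc = sum(1 for c in correct if not c)
        n_cor = sum(1 for c in correct if c)
        rows.append((
            100 * sum(rej) / len(scores),
            100 * np.mean(kept_correct) if kept_correct else np.nan,
            100 * sum(1 for c, r in zip(correct, rej) if r and not c) / n_inc
            if n_inc else 0.0,
            100 * sum(1 for c, r in zip(correct, rej) if r and c) / n_cor
            if n_cor else 0.0,
        ))
    return np.array(rows)


class TestRejection:
    def test_all_correct_hundred_percent(self):
        curve = rejection_analysis([0.1, 0.2, 0.3], [True, True, True],
                                   [0.15, 0.25, 0.5])
        np.testing.assert_allclose(curve.accepted_accuracy_pct, 100.0)

    def test_ten_pair_hand_enumeration(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10)
        correct = rng.random(10) > 0.4
        thresholds = np.sort(rng.random(5))
        curve = rejection_analysis(scores, correct, thresholds)
        expected = _brute_force_curve(scores, correct, thresholds)
        np.testing.assert_allclose(curve.reject_pct, expected[:, 0])
        np.testing.assert_allclose(curve.accepted_accuracy_pct, expected[:, 1])
        np.testing.assert_allclose(curve.incorrect_rejected_pct, expected[:, 2])
        np.testing.assert_allclose(curve.correct_rejected_pct, expected[:, 3])

    def test_threshold_above_max_rejects_nothing(self):
        scores = [0.1, 0.5, 0.9]
        correct = [True, False, True]
        curve = rejection_analysis(scores, correct, [1.0])
        assert curve.reject_pct[0] == 0.0
        assert curve.accepted_accuracy_pct[0] == pytest.approx(100 * 2 / 3)

    def test_reject_fraction_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        correct = rng.random(200) > 0.3
        curve = rejection_analysis(scores, correct, np.linspace(0, 1, 30))
        assert (np.diff(curve.reject_pct) <= 1e-9).all()

    def test_all_rejected_warns_nan(self):
        with pytest.warns(UserWarning):
            curve = rejection_analysis([0.9, 0.8], [True, False], [0.1])
        assert np.isnan(curve.accepted_accuracy_pct[0])

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            rejection_analysis([0.5], [True], [0.9, 0.1])


class TestSelectThreshold:
    def test_perfectly_separable(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        correct = np.array([True, True, True, False, False])
        t = select_threshold(scores, correct, max_correct_rejection=0.0)
        kept = scores <= t
        assert correct[kept].mean() == 1.0
        assert t >= 0.3

    def test_zero_budget_keeps_all_correct(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        correct = rng.random(50) > 0.3
        t = select_threshold(scores, correct, max_correct_rejection=0.0)
        assert t >= scores[correct].max()

    def test_all_correct_rejects_nothing(self):
        scores = np.array([0.4, 0.2, 0.9])
        t = select_threshold(scores, np.array([True, True, True]),
                             max_correct_rejection=0.05)
        assert t == pytest.approx(0.9)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        correct = rng.random(40) > 0.4
        budget = 0.1
        t = select_threshold(scores, correct, budget)
        n_cor = correct.sum()
        best_acc, best_t = -1.0, None
        for cand in np.unique(scores)[::-1]:
            kept = scores <= cand
            if ((~kept) & correct).sum() / n_cor > budget or not kept.any():
                continue
            acc = correct[kept].mean()
            if acc > best_acc:
                best_acc, best_t = acc, cand
        assert t == pytest.approx(best_t)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [], 0.1)


class TestCalibration:
    def test_perfect_predictor_zero_ece_brier(self):
        rep = calibration_report([1.0] * 10, [True] * 10)
        assert rep.ece == pytest.approx(0.0, abs=1e-12)
        assert rep.brier == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_hand_case(self):
        # one nonempty bin: mean confidence 0.8, accuracy 0.5 -> ECE 0.3
        rep = calibration_report([0.8, 0.8], [True, False], n_bins=10)
        assert rep.ece == pytest.approx(0.3, abs=1e-12)

    def test_calibrated_simulation_low_ece(self):
        rng = np.random.default_rng(42)
        conf = rng.uniform(0.5, 1.0, 10_000)
        correct = rng.random(10_000) < conf
        rep = calibration_report(conf, correct, n_bins=10)
        assert rep.ece < 0.02

    def test_bin_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        rep = calibration_report(rng.random(100), rng.random(100) > 0.5)
        assert rep.bin_weight.sum() == pytest.approx(1.0)

    def test_multiclass_brier(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = np.array([0, 1])
        expected = ((0.1 ** 2 + 0.1 ** 2) + (0.2 ** 2 + 0.2 ** 2)) / 2
        assert brier_score(probs, labels) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibration_report([0.5], [True], n_bins=0)
        with pytest.raises(ValueError):
            calibration_report([1.5], [True])
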
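"""Evaluation metrics against brute-force oracles and printed examples."""

import numpy as np
import pytest

from depthplate.errors import (
    EmptyList,
    EmptyUnion,
    NoFoodInTarget,
    ZeroReference,
)
from depthplate.metrics import (
    ConfusionCounts,
    confusion_counts,
    food_segmentation_accuracy,
    global_accuracy,
    intake_error_2d,
    intake_error_3d,
    iou,
    summarize,
    volume_error_stats,
)


def brute_force_counts(target, prediction):
    """Independent oracle: per-pixel Python loop."""
    tp = tn = fp = fn = 0
    for t, p in zip(target.ravel().tolist(), prediction.ravel().tolist()):
        if t and p:
            tp += 1
        elif not t and not p:
            tn += 1
        elif not t and p:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


class TestConfusionCounts:
    def test_identity(self):
        t = np.zeros((25, 40), bool)
        t.ravel()[:100] = True
        c = confusion_counts(t, t)
        assert (c.tp, c.tn, c.fp, c.fn) == (100, 900, 0, 0)

    def test_complement(self):
        t = np.zeros((4, 4), bool)
        t[:2] = True
        c = confusion_counts(t, ~t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 8 and c.fn == 8

    def test_partial_overlap(self):
        t = np.zeros((4, 4), bool)
        p = np.zeros((4, 4), bool)
        t.ravel()[:4] = True
        p.ravel()[2:6] = True
        c = confusion_counts(t, p)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 10)


class TestAccuracies:
    def test_global_accuracy_arithmetic(self):
        assert global_accuracy(ConfusionCounts(90, 5, 3, 2)) == pytest.approx(0.95)

    def test_perfect_and_all_wrong(self):
        assert global_accuracy(ConfusionCounts(10, 90, 0, 0)) == 1.0
        assert global_accuracy(ConfusionCounts(0, 0, 50, 50)) == 0.0

    def test_food_accuracy_is_recall(self):
        assert food_segmentation_accuracy(ConfusionCounts(90, 0, 7, 10)) == pytest.approx(0.9)
        assert food_segmentation_accuracy(ConfusionCounts(5, 0, 99, 0)) == 1.0
        with pytest.raises(NoFoodInTarget):
            food_segmentation_accuracy(ConfusionCounts(0, 10, 3, 0))


class TestIOU:
    def test_examples(self):
        t = np.zeros((4, 4), bool)
        t.ravel()[:4] = True
        assert iou(t, t) == 1.0
        p = np.zeros((4, 4), bool)
        p.ravel()[4:8] = True
        assert iou(t, p) == 0.0
        p2 = np.zeros((4, 4), bool)
        p2.ravel()[2:6] = True
        assert iou(t, p2) == pytest.approx(2 / 6)

    def test_empty_union_raises(self):
        e = np.zeros((4, 4), bool)
        with pytest.raises(EmptyUnion):
            iou(e, e)


class TestOracleEquivalence:
    def test_thousand_random_pairs_exact(self, rng):
        """Counts, accuracies and IOU agree exactly with per-pixel counting."""
        for _ in range(1000):
            t = rng.random((16, 16)) < rng.uniform(0.1, 0.9)
            p = rng.random((16, 16)) < rng.uniform(0.1, 0.9)
            tp, tn, fp, fn = brute_force_counts(t, p)
            c = confusion_counts(t, p)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            assert global_accuracy(c) == (tp + tn) / 256
            if tp + fn:
                assert food_segmentation_accuracy(c) == tp / (tp + fn)
            if tp + fp + fn:
                assert iou(t, p) == tp / (tp + fp + fn)

    def test_iou_bounded_by_recall_and_precision(self, rng):
        for _ in range(200):
            t = rng.random((16, 16)) < 0.4
            p = rng.random((16, 16)) < 0.4
            c = confusion_counts(t, p)
            if c.tp + c.fn == 0 or (c.tp + c.fp + c.fn) == 0:
                continue
            j = iou(t, p)
            assert j <= food_segmentation_accuracy(c) + 1e-12
            if c.tp + c.fp:
                assert j <= c.tp / (c.tp + c.fp) + 1e-12


class TestIntakeErrors:
    def test_perfect_prediction_zero_error(self):
        gt = [1000, 600, 300]
        assert np.allclose(intake_error_2d(gt, gt), 0.0)
        assert np.allclose(intake_error_3d([100.0, 40.0], [100.0, 40.0]), 0.0)

    def test_sign_convention_predicted_minus_target(self):
        """Under-segmented remainder => over-estimated intake => positive error."""
        err = intake_error_2d([1000, 400], [1000, 500])
        assert err[1] == pytest.approx(+10.0)
        err3 = intake_error_3d([100.0, 45.0], [100.0, 40.0])
        assert err3[1] == pytest.approx(-5.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroReference):
            intake_error_2d([0, 0], [0, 0])


class TestVolumeErrorStats:
    def test_identity(self):
        s = volume_error_stats([100.0, 50.0], [100.0, 50.0])
        assert s.mean_absolute_error_ml == 0.0
        assert s.mean_error_bias_ml == 0.0
        assert np.allclose(s.volume_intake_error_ml, 0.0)

    def test_mae_vs_bias(self):
        s = volume_error_stats([102.0, 48.0], [100.0, 50.0])
        assert s.mean_absolute_error_ml == pytest.approx(2.0)
        assert s.mean_error_bias_ml == pytest.approx(0.0)

    def test_constant_offset_cancels_in_intake(self):
        s = volume_error_stats([103.0, 43.0], [100.0, 40.0])
        assert np.allclose(s.volume_intake_error_ml, 0.0)


class TestSummarize:
    def test_textbook_values(self):
        s = summarize([1, 2, 3])
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)

    def test_single_value_warns_sd_zero(self):
        with pytest.warns(UserWarning):
            s = summarize([5.0])
        assert (s.mean, s.sd) == (5.0, 0.0)

    def test_constant_list_and_empty(self):
        assert summarize([4, 4, 4]).sd == 0.0
        with pytest.raises(EmptyList):
            summarize([])
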
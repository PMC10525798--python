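import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adverseg.dataio import BINARY_SCHEME, MULTI_SCHEME
from adverseg.errors import ShapeError, ValidationError
from adverseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    dice,
    evaluate,
    f1,
    iou,
    precision,
    recall,
)


def tally_oracle(pred, truth, label):
    """Independent per-pixel tallying loop."""
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p == label and t == label:
            tp += 1
        elif p == label:
            fp += 1
        elif t == label:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
)


class TestConfusionCounts:
    def test_perfect_agreement(self, rng):
        m = rng.integers(0, 4, (8, 8))
        c = confusion_counts(m, m, 1)
        assert c.fp == 0 and c.fn == 0

    def test_hand_counted_grid(self):
        truth = np.zeros((4, 4), dtype=int)
        truth[:2, :2] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[0, :] = 1
        c = confusion_counts(pred, truth, 1)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 10)

    def test_random_masks_match_oracle(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, (16, 16))
            truth = rng.integers(0, 4, (16, 16))
            for lab in range(4):
                assert confusion_counts(pred, truth, lab) == tally_oracle(
                    pred, truth, lab
                )

    def test_counts_sum_to_total(self, rng):
        pred = rng.integers(0, 4, (13, 7))
        truth = rng.integers(0, 4, (13, 7))
        c = confusion_counts(pred, truth, 2)
        assert c.total == 13 * 7

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), 0)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMetricFormulas:
    def test_dice_arithmetic(self):
        assert dice(ConfusionCounts(6, 2, 2, 0)) == 0.75

    def test_dice_no_overlap(self):
        assert dice(ConfusionCounts(0, 3, 4, 10)) == 0.0

    def test_iou_arithmetic(self):
        assert iou(ConfusionCounts(6, 2, 2, 0)) == 0.6

    def test_identical_masks_iou_one(self, rng):
        m = rng.integers(0, 3, (8, 8))
        assert iou(confusion_counts(m, m, 1)) == 1.0

    def test_recall_precision_f1(self):
        c = ConfusionCounts(2, 2, 2, 10)
        assert recall(c) == 0.5
        assert precision(c) == 0.5
        assert f1(c) == 0.5

    def test_both_empty_convention(self):
        c = ConfusionCounts(0, 0, 0, 16)
        for m in (dice, iou, recall, precision, f1):
            assert m(c) == 1.0

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_dice_equals_f1(self, quad):
        tp, fp, fn, tn = quad
        c = ConfusionCounts(tp, fp, fn, tn)
        assert abs(dice(c) - f1(c)) < 1e-12

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_dice_iou_identity(self, quad):
        tp, fp, fn, tn = quad
        c = ConfusionCounts(tp, fp, fn, tn)
        assert abs(dice(c) - 2 * iou(c) / (1 + iou(c))) < 1e-12

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_iou_le_dice(self, quad):
        c = ConfusionCounts(*quad)
        assert iou(c) <= dice(c) + 1e-15

    @given(counts_strategy)
    @settings(max_examples=200, deadline=None)
    def test_f1_harmonic_mean(self, quad):
        c = ConfusionCounts(*quad)
        p, r = precision(c), recall(c)
        if p + r > 0 and c.tp + c.fp > 0 and c.tp + c.fn > 0:
            assert abs(f1(c) - 2 * p * r / (p + r)) < 1e-12

    def test_permutation_invariance(self, rng):
        pred = rng.integers(0, 4, (10, 10))
        truth = rng.integers(0, 4, (10, 10))
        perm = rng.permutation(100)
        pred_p = pred.ravel()[perm].reshape(10, 10)
        truth_p = truth.ravel()[perm].reshape(10, 10)
        for lab in range(4):
            assert confusion_counts(pred, truth, lab) == confusion_counts(
                pred_p, truth_p, lab
            )


class TestEvaluate:
    def test_perfect(self, rng):
        masks = [rng.integers(0, 4, (8, 8)) for _ in range(3)]
        report = evaluate(masks, masks, MULTI_SCHEME)
        for row in report.per_label.values():
            assert all(v == 1.0 for v in row.values())
        assert all(v == 1.0 for v in report.mean.values())

    def test_single_sample_equals_own_metrics(self, rng):
        pred = rng.integers(0, 4, (8, 8))
        truth = rng.integers(0, 4, (8, 8))
        report = evaluate([pred], [truth], MULTI_SCHEME)
        c = confusion_counts(pred, truth, 1)
        assert report.per_label["left_lung"]["dice"] == dice(c)

    def test_micro_pooling_oracle(self, rng):
        preds = [rng.integers(0, 4, (8, 8)) for _ in range(10)]
        truths = [rng.integers(0, 4, (8, 8)) for _ in range(10)]
        report = evaluate(preds, truths, MULTI_SCHEME)
        for lab in range(1, 4):
            pooled = ConfusionCounts(0, 0, 0, 0)
            for p, t in zip(preds, truths):
                pooled = pooled + tally_oracle(p, t, lab)
            name = MULTI_SCHEME.labels[lab]
            assert report.per_label[name]["dice"] == dice(pooled)
            assert report.per_label[name]["iou"] == iou(pooled)

    def test_macro_differs_from_micro(self, rng):
        preds = [rng.integers(0, 2, (8, 8)) for _ in range(4)]
        truths = [rng.integers(0, 2, (8, 8)) for _ in range(4)]
        micro = evaluate(preds, truths, BINARY_SCHEME, average="micro")
        macro = evaluate(preds, truths, BINARY_SCHEME, average="macro")
        assert micro.average == "micro" and macro.average == "macro"

    def test_mean_excludes_background(self, rng):
        # all-background predictions vs mixed truth: background row is good,
        # organ rows are bad, and the mean reflects only the organ rows
        preds = [np.zeros((8, 8), dtype=int)]
        truths = [np.ones((8, 8), dtype=int)]
        report = evaluate(preds, truths, BINARY_SCHEME)
        assert report.mean["dice"] == 0.0

    def test_csv_layout(self, rng, tmp_path):
        masks = [rng.integers(0, 4, (4, 4))]
        report = evaluate(masks, masks, MULTI_SCHEME)
        text = report.to_csv(tmp_path / "report.csv")
        lines = text.strip().splitlines()
        assert lines[0] == "label,dice,iou,recall,precision,f1"
        assert lines[-1].startswith("mean,")
        assert (tmp_path / "report.csv").exists()

    def test_errors(self, rng):
        with pytest.raises(ValidationError):
            evaluate([], [], MULTI_SCHEME)
        with pytest.raises(ShapeError):
            evaluate([np.zeros((2, 2))], [np.zeros((2, 2)), np.zeros((2, 2))], MULTI_SCHEME)
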
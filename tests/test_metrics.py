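"""Pixel metrics against brute-force oracles, and the HR binned report."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cls_seg.metrics import (ConfusionCounts, confusion, accuracy, dice,
                             hr_table, hsil_recall, evaluate_set, precision,
                             recall, score, specificity)


def _brute_counts(pred, truth):
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestConfusion:
    def test_all_foreground(self):
        m = np.ones((2, 2), bool)
        c = confusion(m, m)
        assert (c.TP, c.TN, c.FP, c.FN) == (4, 0, 0, 0)

    def test_all_missed(self):
        t = np.ones((3, 5), bool)
        c = confusion(np.zeros_like(t), t)
        assert c.FN == 15 and c.TP == 0

    def test_random_pair_matches_enumeration(self):
        rng = np.random.default_rng(0)
        pred = rng.random((4, 4)) > 0.5
        truth = rng.random((4, 4)) > 0.5
        c = confusion(pred, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == _brute_counts(pred, truth)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestFormulas:
    def test_perfect_prediction(self):
        c = ConfusionCounts(TP=4, TN=0, FP=0, FN=0)
        assert dice(c) == recall(c) == precision(c) == 1.0

    def test_hand_computed_counts(self):
        c = ConfusionCounts(TP=2, FP=1, FN=1, TN=12)
        assert dice(c) == pytest.approx(4 / 6)
        assert accuracy(c) == pytest.approx(14 / 16)
        assert recall(c) == pytest.approx(2 / 3)
        assert precision(c) == pytest.approx(2 / 3)
        assert specificity(c) == pytest.approx(12 / 13)

    def test_empty_vs_empty_policy(self):
        c = ConfusionCounts(TP=0, FP=0, FN=0, TN=16)
        assert dice(c) == 1.0 and recall(c) == 1.0 and precision(c) == 1.0

    def test_recall_undefined_with_fp_but_no_truth(self):
        assert recall(ConfusionCounts(TP=0, FP=3, FN=0, TN=13)) is None

    def test_score_is_arithmetic_mean(self):
        assert score(1, 1) == 1.0
        assert score(0, 1) == 0.5
        assert score(0.7371, 0.7802) == pytest.approx(0.75865)

    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_dice_is_f1_of_pixel_counts(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        d = dice(c)
        assert 0.0 <= d <= 1.0
        p, r = precision(c), recall(c)
        if r is not None and p + r > 0:
            f1 = 2 * p * r / (p + r)
            assert d == pytest.approx(f1, abs=1e-12)
        assert accuracy(c) == (tp + tn) / max(c.total, 1) if c.total else True

    def test_metrics_match_oracle_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pred = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
            truth = rng.random((8, 8)) > rng.uniform(0.2, 0.8)
            c = confusion(pred, truth)
            tp, tn, fp, fn = _brute_counts(pred, truth)
            assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
            if fp + fn + 2 * tp:
                assert dice(c) == pytest.approx(2 * tp / (fp + fn + 2 * tp))
            assert accuracy(c) == pytest.approx((tp + tn) / 64)
            if tn + fp:
                assert specificity(c) == pytest.approx(tn / (tn + fp))


class TestEvaluateSet:
    def test_identical_perfect_pairs(self):
        t = np.zeros((4, 4), bool)
        t[1:3, 1:3] = True
        rep = evaluate_set([t, t], [t, t])
        assert rep["dice"] == (1.0, 0.0)
        assert rep["accuracy"] == 1.0

    def test_single_image_zero_std(self):
        t = np.ones((4, 4), bool)
        p = t.copy()
        p[0, 0] = False
        rep = evaluate_set([p], [t])
        assert rep["dice"][1] == 0.0

    def test_three_pairs_match_hand_computation(self):
        rng = np.random.default_rng(7)
        preds = [rng.random((4, 4)) > 0.5 for _ in range(3)]
        truths = [rng.random((4, 4)) > 0.4 for _ in range(3)]
        rep = evaluate_set(preds, truths)
        dices, accs = [], []
        pooled = [0, 0, 0, 0]
        for p, t in zip(preds, truths):
            tp, tn, fp, fn = _brute_counts(p, t)
            pooled = [pooled[0] + tp, pooled[1] + tn,
                      pooled[2] + fp, pooled[3] + fn]
            dices.append(2 * tp / (fp + fn + 2 * tp) if fp + fn + tp else 1.0)
            accs.append((tp + tn) / 16)
        mean = sum(dices) / 3
        var = sum((d - mean) ** 2 for d in dices) / 3  # population std
        assert rep["dice"][0] == pytest.approx(mean)
        assert rep["dice"][1] == pytest.approx(np.sqrt(var))
        assert rep["accuracy"] == pytest.approx(
            (pooled[0] + pooled[1]) / 48)

    def test_pairing_mismatch(self):
        with pytest.raises(ValueError, match="paired"):
            evaluate_set([np.zeros((2, 2))], [])


class TestHsilRecall:
    def test_full_coverage(self):
        t = np.zeros((6, 6), bool)
        t[2:4, 2:4] = True
        assert hsil_recall(np.ones((6, 6), bool), t) == 1.0

    def test_no_coverage(self):
        t = np.zeros((6, 6), bool)
        t[2:4, 2:4] = True
        assert hsil_recall(np.zeros((6, 6), bool), t) == 0.0

    def test_partial_coverage_pixel_counting(self):
        t = np.zeros((4, 4), bool)
        t[0, :4] = True
        t[1, :4] = True  # |A_H| = 8
        p = np.zeros((4, 4), bool)
        p[0, :4] = True
        p[1, :2] = True  # 6 covered
        assert hsil_recall(p, t) == pytest.approx(0.75)

    def test_empty_truth_errors(self):
        with pytest.raises(ValueError, match="empty"):
            hsil_recall(np.ones((3, 3), bool), np.zeros((3, 3), bool))


class TestHRTable:
    def test_reproduces_clinical_distribution(self):
        # 152 cases binned 146/2/0/3/1 from the highest bin down
        hrs = ([0.95] * 146 + [0.85] * 2 + [0.65] * 3 + [0.3])
        rows = hr_table(hrs)
        assert [r["count"] for r in rows] == [146, 2, 0, 3, 1]
        assert [r["percentage"] for r in rows] == [96.05, 1.32, 0.0, 1.97, 0.66]

    def test_all_perfect(self):
        rows = hr_table([1.0] * 10)
        assert rows[0]["count"] == 10 and rows[0]["percentage"] == 100.0

    def test_boundary_value_goes_to_lower_bin(self):
        rows = hr_table([0.9])
        assert rows[1]["count"] == 1 and rows[0]["count"] == 0

    def test_zero_in_lowest_bin(self):
        rows = hr_table([0.0])
        assert rows[-1]["count"] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="HR"):
            hr_table([1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_percentages_sum_to_100(self, hrs):
        rows = hr_table(hrs)
        assert sum(r["count"] for r in rows) == len(hrs)
        assert sum(r["percentage"] for r in rows) == pytest.approx(100, abs=0.05)
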
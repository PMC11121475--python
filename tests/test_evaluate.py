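"""Diagnostic metrics and ROC/AUC against hand tallies and a pair-counting oracle."""

import numpy as np
import pytest

from thermofract.evaluate import (
    ConfusionMatrix,
    confusion,
    evaluate_scores,
    metrics,
    roc_auc,
)


def pair_counting_auc(labels, scores):
    """Brute-force Mann-Whitney AUC: wins + half-ties over all +/- pairs."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        y = [1] * 10 + [0] * 10
        cm = confusion(y, y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_all_predicted_fracture(self):
        y = [1] * 10 + [0] * 10
        cm = confusion(y, [1] * 20)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (10, 10, 0, 0)

    def test_eight_item_hand_tally(self):
        labels = [1, 1, 1, 0, 0, 0, 1, 0]
        preds =  [1, 0, 1, 0, 1, 0, 0, 0]
        cm = confusion(labels, preds)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 3, 2)
        assert cm.total == 8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_hand_computed_report(self):
        rep = metrics(ConfusionMatrix(tp=50, fp=10, tn=30, fn=10))
        assert rep.sensitivity == pytest.approx(83.3, abs=0.05)
        assert rep.specificity == pytest.approx(75.0)
        assert rep.ppv == pytest.approx(83.3, abs=0.05)
        assert rep.npv == pytest.approx(75.0)
        assert rep.accuracy == pytest.approx(80.0)

    def test_error_free_matrix_gives_all_hundred(self):
        rep = metrics(ConfusionMatrix(tp=7, fp=0, tn=9, fn=0))
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv, rep.accuracy) == \
            (100.0, 100.0, 100.0, 100.0, 100.0)

    @pytest.mark.parametrize("tp", [1, 5, 400])
    def test_tp_equals_fn_pins_sensitivity_at_fifty(self, tp):
        rep = metrics(ConfusionMatrix(tp=tp, fp=3, tn=2, fn=tp))
        assert rep.sensitivity == pytest.approx(50.0)

    def test_zero_denominators_reported_as_undefined(self):
        rep = metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert rep.sensitivity is None  # no positives to be sensitive to
        assert rep.ppv is None
        assert rep.specificity == 100.0
        empty = metrics(ConfusionMatrix(0, 0, 0, 0))
        assert empty.accuracy is None

    def test_balanced_classes_tie_accuracy_to_mean_of_sens_spec(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp = int(rng.integers(0, 50))
            tn = int(rng.integers(0, 50))
            cm = ConfusionMatrix(tp=tp, fn=50 - tp, tn=tn, fp=50 - tn)
            rep = metrics(cm)
            assert rep.accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_give_auc_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_four_point_example_matches_pair_oracle(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]
        _, auc = roc_auc(labels, scores)
        assert auc == 0.75 == pair_counting_auc(labels, scores)

    def test_random_scores_match_pair_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            _, auc = roc_auc(labels, scores)
            assert auc == pytest.approx(pair_counting_auc(labels, scores), abs=1e-12)

    def test_trapezoid_over_roc_points_equals_pair_auc(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        points, auc = roc_auc(labels, scores)
        fpr, tpr = np.array(points).T
        assert np.trapezoid(tpr, fpr) == pytest.approx(auc, abs=1e-12)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestEvaluateScores:
    def test_label_swap_duality(self):
        # swapping classes (and the corresponding predictions) exchanges
        # sensitivity<->specificity and ppv<->npv; scoring the old positive
        # class against the swapped labels flips the AUC to 1 - auc
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        preds = (scores > 0.5).astype(int)
        rep = metrics(confusion(labels, preds))
        swapped = metrics(confusion(1 - labels, 1 - preds))
        assert swapped.sensitivity == pytest.approx(rep.specificity)
        assert swapped.specificity == pytest.approx(rep.sensitivity)
        assert swapped.ppv == pytest.approx(rep.npv)
        assert swapped.npv == pytest.approx(rep.ppv)
        _, auc = roc_auc(labels, scores)
        _, auc_swapped = roc_auc(1 - labels, scores)
        assert auc_swapped == pytest.approx(1 - auc, abs=1e-12)

    def test_exact_half_probability_predicts_non_fracture(self):
        rep = evaluate_scores([1, 0], [0.5, 0.5])
        assert rep.confusion.fn == 1 and rep.confusion.tn == 1
        assert rep.confusion.tp == rep.confusion.fp == 0

    def test_report_serializes(self, tmp_path):
        rep = evaluate_scores([0, 1, 0, 1], [0.2, 0.9, 0.4, 0.7])
        rep.save_json(tmp_path / "metrics.json")
        import json
        data = json.loads((tmp_path / "metrics.json").read_text())
        assert data["accuracy"] == 100.0 and data["auc"] == 1.0
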
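"""Confusion-matrix metrics, ROC/AUC duality, fold aggregation."""

import numpy as np
import pytest

from keranet.metrics import (
    ConfusionCounts,
    PredictionRecord,
    UndefinedMetricError,
    accuracy,
    aggregate_folds,
    confusion,
    cross_entropy,
    evaluate_predictions,
    mcc,
    roc_auc,
    sensitivity,
    specificity,
)


def brute_force_from_counts(c: ConfusionCounts):
    """Independent oracle: expand counts to 0/1 vectors and recount.

    MCC is evaluated as the Pearson correlation between the true and
    predicted 0/1 vectors (mapped to 0 when undefined).
    """
    y = np.array([1] * (c.TP + c.FN) + [0] * (c.TN + c.FP))
    pred = np.array([1] * c.TP + [0] * c.FN + [0] * c.TN + [1] * c.FP)
    out = {"accuracy": float(np.mean(y == pred))}
    if (y == 1).any():
        out["sensitivity"] = float(pred[y == 1].mean())
    if (y == 0).any():
        out["specificity"] = float(1 - pred[y == 0].mean())
    if y.std() == 0 or pred.std() == 0:
        out["mcc"] = 0.0
    else:
        out["mcc"] = float(np.corrcoef(y, pred)[0, 1])
    return out


class TestConfusion:
    def test_direct_classification(self):
        c = confusion([1, 0], [0.9, 0.1])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_zero_threshold_predicts_everything_positive(self):
        c = confusion([1, 1, 0, 0, 0], [0.2, 0.9, 0.1, 0.5, 0.0], threshold=0.0)
        assert (c.TP, c.FP, c.TN, c.FN) == (2, 3, 0, 0)

    def test_counts_conserve_n(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        c = confusion(y, p)
        assert c.total == 50

    def test_accepts_prediction_records(self):
        preds = [PredictionRecord(y=1, p=0.9), PredictionRecord(y=0, p=0.2)]
        assert accuracy(confusion(preds)) == 1.0


class TestScalarMetrics:
    @pytest.mark.parametrize("counts, expected", [
        ((5, 0, 5, 0), 1.0),
        ((3, 1, 4, 2), 0.7),
        ((0, 1, 0, 1), 0.0),
    ])
    def test_accuracy_arithmetic(self, counts, expected):
        tp, fp, tn, fn = counts
        assert accuracy(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_sensitivity_specificity_arithmetic(self):
        c = ConfusionCounts(TP=9, FP=2, TN=8, FN=1)
        assert sensitivity(c) == pytest.approx(0.9)
        assert specificity(c) == pytest.approx(0.8)

    def test_degenerate_margins_raise(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(TP=0, FP=2, TN=3, FN=0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(TP=1, FP=0, TN=0, FN=1))

    @pytest.mark.parametrize("counts, expected", [
        ((5, 0, 5, 0), 1.0),                      # perfect prediction
        ((0, 5, 0, 5), -1.0),                     # total disagreement
        ((3, 1, 4, 2), 10.0 / np.sqrt(600.0)),    # Pearson oracle value
        ((4, 0, 0, 0), 0.0),                      # empty margins → 0
    ])
    def test_mcc_reference_values(self, counts, expected):
        tp, fp, tn, fn = counts
        assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_exhaustive_agreement_with_expanded_vector_oracle(self):
        # spot-check grid here; the full 7^4 sweep runs in the acceptance suite
        for tp in range(0, 7, 2):
            for fp in range(0, 7, 3):
                for tn in range(0, 7, 2):
                    for fn in range(0, 7, 3):
                        if tp + fp + tn + fn == 0:
                            continue
                        c = ConfusionCounts(tp, fp, tn, fn)
                        oracle = brute_force_from_counts(c)
                        assert accuracy(c) == pytest.approx(oracle["accuracy"])
                        assert mcc(c) == pytest.approx(oracle["mcc"])


class TestCrossEntropy:
    def test_perfect_confidence_is_near_zero(self):
        assert cross_entropy([1], [1.0]) == pytest.approx(0.0, abs=1e-6)

    def test_half_confidence_is_ln_two(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_symmetry_under_label_swap(self, rng):
        y = rng.integers(0, 2, 30)
        p = rng.random(30)
        assert cross_entropy(y, p) == pytest.approx(cross_entropy(1 - y, 1 - p))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_identical_scores_give_auc_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.4, 0.4, 0.4, 0.4])
        assert auc == 0.5

    def test_worked_example_075(self):
        # 4 (pos, neg) pairs: 3 concordant, 1 discordant → 0.75
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.5, 0.6])

    def test_pair_counting_equals_trapezoid_area(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
            points, auc = roc_auc(y, p)
            trap = np.trapezoid(points[:, 1], points[:, 0])
            assert auc == pytest.approx(trap, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p = rng.random(60).round(1)
        _, auc = roc_auc(y, p)
        assert auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestAggregation:
    def test_zero_variance(self):
        s = aggregate_folds([1.0] * 5)
        assert s.mean == 1.0
        assert s.ci_half_width == 0.0

    def test_hand_computed_ci(self):
        # t(0.975, 4) = 2.776, sd = 0.01581 → half-width 0.0196
        s = aggregate_folds([0.90, 0.92, 0.94, 0.91, 0.93])
        assert s.mean == pytest.approx(0.92)
        assert s.ci_half_width == pytest.approx(0.0196, abs=5e-4)

    def test_permutation_invariance(self):
        a = aggregate_folds([0.1, 0.5, 0.9])
        b = aggregate_folds([0.9, 0.1, 0.5])
        assert a.mean == b.mean
        assert a.ci_half_width == pytest.approx(b.ci_half_width)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([0.5])


class TestRangeInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts = st.tuples(*[st.integers(0, 50)] * 4).filter(lambda c: sum(c) > 0)

    @given(counts)
    @settings(deadline=None, derandomize=True)
    def test_rate_metrics_stay_in_unit_interval_and_mcc_in_pm1(self, c):
        counts = ConfusionCounts(*c)
        assert 0.0 <= accuracy(counts) <= 1.0
        assert -1.0 <= mcc(counts) <= 1.0
        if counts.TP + counts.FN > 0:
            assert 0.0 <= sensitivity(counts) <= 1.0
        if counts.TN + counts.FP > 0:
            assert 0.0 <= specificity(counts) <= 1.0

    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=2, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_auc_in_unit_interval_when_defined(self, pairs):
        y = np.array([a for a, _ in pairs])
        p = np.array([b for _, b in pairs])
        if y.min() == y.max():
            return
        _, auc = roc_auc(y, p)
        assert 0.0 <= auc <= 1.0


def test_evaluate_predictions_is_consistent(rng):
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    p = rng.random(40)
    out = evaluate_predictions(y, p)
    c = confusion(y, p)
    assert out["accuracy"] == accuracy(c)
    assert out["mcc"] == mcc(c)
    assert set(out) == {"accuracy", "loss", "auc", "sensitivity", "specificity", "mcc"}
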
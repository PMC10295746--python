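"""Fold construction, learning-rate schedule, fold training and CV."""

import numpy as np
import pytest

from keranet.architecture import ModelConfig
from keranet.augment import AugmentConfig
from keranet.train import (
    FoldAssignment,
    LRState,
    TrainConfig,
    lr_schedule_step,
    make_folds,
    run_cv,
    train_fold,
)

FAST_AUG = AugmentConfig(rotation_range_deg=0, width_shift_frac=0, height_shift_frac=0,
                         zoom_range=0, horizontal_flip=True, vertical_flip=False)
TINY_MODEL = ModelConfig(input_size=(12, 12, 3), truncate_after_block=1,
                         width_multiplier=0.25)


class TestMakeFolds:
    def test_balanced_ten_records_five_folds(self):
        labels = np.array([1] * 5 + [0] * 5)
        fa = make_folds(labels, k=5, seed=0)
        for fold in fa.folds:
            assert len(fold) == 2
            assert sorted(labels[list(fold)]) == [0, 1]

    def test_partition_property(self, rng):
        for n in (10, 23, 37, 50):
            labels = rng.integers(0, 2, n)
            while min(np.bincount(labels, minlength=2)) < 5:
                labels = rng.integers(0, 2, n)
            fa = make_folds(labels, k=5, seed=3)
            flat = sorted(i for fold in fa.folds for i in fold)
            assert flat == list(range(n))

    def test_twelve_records_fold_sizes(self):
        labels = np.array([0, 1] * 6)
        fa = make_folds(labels, k=5, seed=1)
        assert sorted(len(f) for f in fa.folds) == [2, 2, 2, 3, 3]

    def test_per_class_fold_sizes_differ_by_at_most_one(self, rng):
        labels = np.array([1] * 13 + [0] * 29)
        fa = make_folds(labels, k=5, seed=9)
        for cls in (0, 1):
            sizes = [int(np.sum(labels[list(f)] == cls)) for f in fa.folds]
            assert max(sizes) - min(sizes) <= 1

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([1] * 3 + [0] * 20)
        with pytest.raises(ValueError):
            make_folds(labels, k=5, seed=0)

    def test_disjointness_enforced_by_type(self):
        with pytest.raises(ValueError):
            FoldAssignment(folds=((0, 1), (1, 2)))

    def test_train_indices_complement_validation(self):
        labels = np.array([0, 1] * 10)
        fa = make_folds(labels, k=4, seed=2)
        for fold_id, val in enumerate(fa.folds):
            train = fa.train_indices(fold_id)
            assert set(train) | set(val) == set(range(20))
            assert set(train) & set(val) == set()


class TestLRSchedule:
    def _trace(self, accs, cfg=TrainConfig()):
        state = LRState(current_lr=cfg.lr_initial)
        lrs = []
        history = []
        for acc in accs:
            history.append(acc)
            lrs.append(state.current_lr)
            state = lr_schedule_step(history, state, cfg)
        return lrs, state

    def test_stagnation_halves_after_two_epochs(self):
        lrs, state = self._trace([0.8, 0.8, 0.8])
        assert lrs == [0.01, 0.01, 0.01]
        assert state.current_lr == 0.005

    def test_repeated_stagnation_floors_at_1e_minus_5(self):
        _, state = self._trace([0.8] + [0.8] * 40)
        assert state.current_lr == pytest.approx(1e-5)

    def test_halving_sequence_is_exact(self):
        cfg = TrainConfig()
        state = LRState(current_lr=cfg.lr_initial, best_acc=1.0)  # permanently stagnant
        seen = [state.current_lr]
        for epoch in range(30):
            state = lr_schedule_step([0.5] * (epoch + 1), state, cfg)
            seen.append(state.current_lr)
        expected = [0.01 * 0.5 ** i for i in range(11)]
        expected = [max(v, 1e-5) for v in expected]
        halvings = sorted(set(seen), reverse=True)
        assert halvings == sorted(set(expected), reverse=True)

    def test_strict_improvement_keeps_lr(self):
        lrs, state = self._trace([0.5, 0.6, 0.7, 0.8])
        assert set(lrs) == {0.01}
        assert state.current_lr == 0.01

    def test_tie_counts_as_stagnation(self):
        _, state = self._trace([0.7, 0.7, 0.7])
        assert state.current_lr == 0.005


def _toy_data(rng, n=24, size=12):
    """Linearly separable color-signal images: class 1 is redder."""
    y = np.array([0, 1] * (n // 2))
    x = rng.random((n, size, size, 3)) * 0.2 + 0.4
    x[y == 1, :, :, 0] += 0.25
    return np.clip(x, 0, 1), y


class TestTrainFold:
    def test_history_lr_is_non_increasing_from_001(self, rng):
        x, y = _toy_data(rng)
        res = train_fold((x[:16], y[:16]), (x[16:], y[16:]), TINY_MODEL,
                         TrainConfig(epochs=4, batch_size=8), FAST_AUG, seed=0)
        lrs = [h["lr"] for h in res.history]
        assert lrs[0] == 0.01
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or b == pytest.approx(max(a * 0.5, 1e-5))

    def test_one_prediction_per_validation_record(self, rng):
        x, y = _toy_data(rng)
        res = train_fold((x[:16], y[:16]), (x[16:], y[16:]), TINY_MODEL,
                         TrainConfig(epochs=2, batch_size=8), FAST_AUG, seed=0)
        assert len(res.p_ak) == 8
        assert len(res.history) == 2

    def test_best_epoch_has_max_val_accuracy(self, rng):
        x, y = _toy_data(rng)
        res = train_fold((x[:16], y[:16]), (x[16:], y[16:]), TINY_MODEL,
                         TrainConfig(epochs=5, batch_size=8), FAST_AUG, seed=1)
        accs = [h["val_accuracy"] for h in res.history]
        assert accs[res.best_epoch] == max(accs)
        assert res.best_epoch == accs.index(max(accs))  # first on ties

    def test_single_class_training_set_rejected(self, rng):
        x, y = _toy_data(rng)
        with pytest.raises(ValueError):
            train_fold((x[y == 1], y[y == 1]), (x[:4], y[:4]), TINY_MODEL,
                       TrainConfig(epochs=1), FAST_AUG, seed=0)

    def test_learns_separable_signal(self, rng):
        x, y = _toy_data(rng, n=40)
        res = train_fold((x[:30], y[:30]), (x[30:], y[30:]), TINY_MODEL,
                         TrainConfig(epochs=6, batch_size=10), FAST_AUG, seed=3)
        best = max(h["val_accuracy"] for h in res.history)
        assert best >= 0.9


class TestRunCV:
    def _run(self, small_corpus, seed=0):
        from keranet.preprocess import PreprocessConfig
        from keranet.train import load_tensors

        _, index = small_corpus
        pre = PreprocessConfig(target_size=(12, 12), clahe_tile_grid=(2, 2))
        return run_cv(
            index,
            pre_cfg=pre,
            model_cfg=TINY_MODEL,
            train_cfg=TrainConfig(epochs=2, batch_size=8, k_folds=2, seed=seed),
            aug_cfg=FAST_AUG,
        )

    def test_report_has_k_fold_rows_and_all_records(self, small_corpus):
        report = self._run(small_corpus)
        assert report.k == 2
        assert len(report.fold_metrics) == 2
        ids = [p["record_id"] for p in report.predictions]
        assert sorted(ids) == sorted(r.image_id for _, index in [small_corpus]
                                     for r in index.records)
        assert len(set(ids)) == len(ids)

    def test_identical_seeds_identical_reports(self, small_corpus):
        a = self._run(small_corpus, seed=11)
        b = self._run(small_corpus, seed=11)
        assert a.to_dict() == b.to_dict()

    def test_aggregates_recomputable_from_fold_rows(self, small_corpus):
        from keranet.metrics import aggregate_folds

        report = self._run(small_corpus)
        for name, summary in report.summaries.items():
            again = aggregate_folds([row[name] for row in report.fold_metrics])
            assert summary["mean"] == pytest.approx(again.mean)
            assert summary["ci_half_width"] == pytest.approx(again.ci_half_width)
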
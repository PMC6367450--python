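"""Fold assignment, losses, metrics, training loop and transfer."""

import numpy as np
import pytest

from megdecode.autodiff import Tensor
from megdecode.data import TrialSet
from megdecode.scnn import SCNNConfig
from megdecode.training import (
    TrainConfig,
    assign_folds,
    build_model,
    class_weights,
    confusion_matrix,
    cross_entropy,
    hyper_search,
    one_off_accuracy,
    smooth_labels,
    train_model,
    transfer_evaluate,
)


class TestAssignFolds:
    def test_one_subject_per_fold(self):
        plan = assign_folds({"a": 10, "b": 8, "c": 6, "d": 4, "e": 2}, 5)
        assert sorted(plan.fold_totals, reverse=True) == [10, 8, 6, 4, 2]
        assert len(set(plan.fold_of_subject.values())) == 5

    def test_symmetric_counts_balance_exactly(self):
        plan = assign_folds({s: 5 for s in range(10)}, 5)
        assert plan.fold_totals == [10] * 5

    def test_greedy_pairing(self):
        plan = assign_folds({"a": 9, "b": 7, "c": 5, "d": 3}, 2)
        assert sorted(plan.fold_totals) == [12, 12]
        assert plan.fold_of_subject["a"] == plan.fold_of_subject["d"]

    def test_test_subjects_in_no_fold(self):
        plan = assign_folds({s: 3 for s in range(8)}, 2, test_subjects=[0, 1])
        assert 0 not in plan.fold_of_subject and 1 not in plan.fold_of_subject
        assert plan.test_subjects == frozenset({0, 1})

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            assign_folds({"a": 1, "b": 1}, 3)


class TestLossesAndMetrics:
    def test_class_weights_formula(self):
        w = class_weights([0] * 25 + [1] * 75)
        assert w == {0: 0.75, 1: 0.25}

    def test_equal_classes_get_half(self):
        w = class_weights([0, 0, 1, 1])
        assert w == {0: 0.5, 1: 0.5}

    def test_majority_share_complement(self):
        # a 38.13% majority share yields penalty 0.6187
        labels = [0] * 3813 + [1] * 3100 + [2] * 3087
        assert class_weights(labels)[0] == pytest.approx(0.6187, abs=1e-4)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])

    def test_smooth_labels_interior(self):
        assert smooth_labels(3, 7).tolist() == [0, 0, 0.2, 0.6, 0.2, 0, 0]

    def test_smooth_labels_boundaries(self):
        assert smooth_labels(0, 7).tolist() == [0.8, 0.2, 0, 0, 0, 0, 0]
        assert smooth_labels(6, 7).tolist() == [0, 0, 0, 0, 0, 0.2, 0.8]

    @pytest.mark.parametrize("k,n", [(0, 2), (1, 2), (2, 5), (4, 5), (3, 9)])
    def test_smooth_labels_sum_to_one(self, k, n):
        assert smooth_labels(k, n).sum() == pytest.approx(1.0)

    def test_one_off_accuracy_examples(self):
        assert one_off_accuracy([0, 3, 6], [1, 5, 6]) == pytest.approx(2 / 3)
        assert one_off_accuracy([1, 2], [1, 2]) == 1.0
        assert one_off_accuracy([0, 0], [2, 5]) == 0.0

    def test_one_off_never_below_plain_accuracy(self, rng):
        t = rng.integers(0, 7, 200)
        p = rng.integers(0, 7, 200)
        assert one_off_accuracy(t, p) >= np.mean(t == p)

    def test_confusion_matrix_rates(self):
        rates, counts = confusion_matrix([0, 0], [0, 1], 2)
        assert rates[0].tolist() == [0.5, 0.5]
        assert counts.sum() == 2

    def test_confusion_matrix_perfect_is_identity(self):
        rates, _ = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
        assert np.allclose(rates, np.eye(3))

    def test_confusion_matrix_empty_class_row_zero(self, caplog):
        rates, _ = confusion_matrix([0, 0], [0, 0], 3)
        assert np.allclose(rates[1], 0) and np.allclose(rates[2], 0)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)

    def test_class_weighted_loss_scaling(self, rng):
        """Equal 2-class counts: weighted loss = 0.5 x unweighted loss."""
        logits = Tensor(rng.normal(size=(8, 2)))
        targets = np.eye(2)[[0, 1] * 4]
        plain = cross_entropy(logits, targets).data
        w = class_weights([0, 1] * 4)
        weighted = cross_entropy(logits, targets, np.array([w[k] for k in [0, 1] * 4])).data
        assert weighted == pytest.approx(0.5 * plain)


def _separable_trialset(rng, n_subjects=6, per_subject=8, T=30, C=4, offset=1.0):
    """Class 1 carries a DC offset on channel 0 (linearly separable)."""
    n = n_subjects * per_subject
    data = rng.normal(size=(n, T, C))
    subjects = np.repeat(np.arange(n_subjects), per_subject)
    labels = (subjects >= n_subjects // 2).astype(int)
    data[labels == 1, :, 0] += offset
    return TrialSet(data, labels, subjects, np.zeros(n, int), np.full(n, T // 2), 100.0)


def _small_cfg(C=4):
    return SCNNConfig(spatial_layers=((C, 3),), temporal_filters=3,
                      temporal_kernel_taps=5, pool_width=5, activation="relu",
                      n_classes=2, seed=0)


class TestTrainModel:
    def test_untrained_model_is_at_chance(self, rng):
        ts = _separable_trialset(rng)
        plan = assign_folds({s: 8 for s in range(4)}, 2, test_subjects=[0, 5])
        res = train_model(_small_cfg(), ts, plan, TrainConfig(epochs=0, seed=0))
        accs = [r.test_accuracy for r in res]
        # 16 test trials: 3 s.e. of chance ~ 0.5 +/- 0.375
        assert all(0.1 <= a <= 0.9 for a in accs)

    def test_separable_data_reaches_high_training_accuracy(self, rng):
        from megdecode.training import fit_fold, predict

        ts = _separable_trialset(rng, offset=2.0)
        cfg = _small_cfg()
        model = build_model(cfg, ts.n_samples, ts.n_channels)
        fit_fold(model, ts, TrainConfig(epochs=20, learning_rate=1e-2, batch_size=16, seed=0), cfg)
        assert np.mean(predict(model, ts.data) == ts.labels) == 1.0

    def test_subject_splits_never_leak(self, rng):
        ts = _separable_trialset(rng)
        plan = assign_folds({s: 8 for s in range(4)}, 2, test_subjects=[0, 5])
        for f in range(plan.n_folds):
            val = set(plan.fold_subjects(f))
            train = {s for s, ff in plan.fold_of_subject.items() if ff != f}
            assert not val & train
            assert not val & plan.test_subjects
            assert not train & plan.test_subjects

    def test_fold_results_report_heldout_accuracy(self, rng):
        ts = _separable_trialset(rng, offset=2.0)
        plan = assign_folds({s: 8 for s in range(1, 5)}, 2, test_subjects=[0, 5])
        res = train_model(
            _small_cfg(), ts, plan,
            TrainConfig(epochs=15, learning_rate=1e-2, batch_size=16, seed=0),
        )
        assert len(res) == 2
        assert all(r.status == "ok" for r in res)
        assert np.mean([r.test_accuracy for r in res]) > 0.8


class TestTransfer:
    def test_single_class_head_predicts_that_class(self, rng):
        ts = _separable_trialset(rng)
        model = build_model(_small_cfg(), ts.n_samples, ts.n_channels)
        tr = ts.select(ts.subject_ids <= 2)
        tr = TrialSet(tr.data, np.zeros(tr.n_trials, int), tr.subject_ids,
                      tr.task_ids, tr.event_index, tr.sampling_rate)
        te = ts.select(ts.subject_ids > 2)
        te = TrialSet(te.data, np.zeros(te.n_trials, int), te.subject_ids,
                      te.task_ids, te.event_index, te.sampling_rate)
        assert transfer_evaluate(model, tr, te) == 1.0

    def test_subject_overlap_rejected(self, rng):
        ts = _separable_trialset(rng)
        model = build_model(_small_cfg(), ts.n_samples, ts.n_channels)
        with pytest.raises(ValueError, match="leakage"):
            transfer_evaluate(model, ts, ts)

    def test_random_features_beat_majority_rate_on_separable_data(self, rng):
        ts = _separable_trialset(rng, offset=2.0)
        model = build_model(_small_cfg(), ts.n_samples, ts.n_channels)
        tr = ts.select(ts.subject_ids % 2 == 0)
        te = ts.select(ts.subject_ids % 2 == 1)
        acc = transfer_evaluate(model, tr, te)
        majority = max(np.mean(te.labels == 0), np.mean(te.labels == 1))
        assert acc >= majority

    def test_trained_features_beat_random_features(self, rng):
        """Averaged over seeds, a trained frozen front-end transfers at least
        as well as a random frozen front-end."""
        from megdecode.training import fit_fold

        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            ts = _separable_trialset(r, offset=0.8)
            tr = ts.select(ts.subject_ids % 2 == 0)
            te = ts.select(ts.subject_ids % 2 == 1)
            cfg = _small_cfg()
            random_model = build_model(cfg, ts.n_samples, ts.n_channels)
            acc_rand = transfer_evaluate(random_model, tr, te, seed=seed)
            trained = build_model(cfg, ts.n_samples, ts.n_channels)
            fit_fold(trained, tr, TrainConfig(epochs=10, learning_rate=1e-2,
                                              batch_size=16, seed=seed), cfg)
            acc_tr = transfer_evaluate(trained, tr, te, seed=seed)
            diffs.append(acc_tr - acc_rand)
        assert np.mean(diffs) >= 0.0


class TestHyperSearch:
    def test_quadratic_recovery_within_ten_percent(self):
        best, score, log = hyper_search(
            {"x": ("uniform", -5.0, 5.0)}, lambda c: (c["x"] - 2.0) ** 2, 100, seed=0
        )
        assert abs(best["x"] - 2.0) <= 0.5  # within 10% of the search range scale
        assert len(log) == 100

    def test_single_iteration_returns_sampled_config(self):
        best, score, log = hyper_search(
            {"lr": ("loguniform", 1e-4, 1e-1), "act": ("choice", ["relu", "selu"])},
            lambda c: 1.0,
            1,
            seed=3,
        )
        assert len(log) == 1 and best == log[0]["config"]
        assert best["act"] in ("relu", "selu")

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            hyper_search({"x": ("uniform", 0, 1)}, lambda c: 0.0, 0)

    def test_pluggable_driver(self):
        def driver(space, objective, n_iter, seed):
            cfg = {"x": 0.0}
            return cfg, objective(cfg), [{"config": cfg, "score": objective(cfg)}]

        best, score, log = hyper_search({"x": ("uniform", -1, 1)},
                                        lambda c: c["x"] ** 2, 5, driver=driver)
        assert best == {"x": 0.0} and score == 0.0
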
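import numpy as np
import pytest

from mseienet import (
    AugmentationConfig,
    ConfusionMatrix,
    SyntheticConfig,
    TrainConfig,
    confusion_matrix,
    generate_mi_trials,
    global_cv,
    hyperparameter_grid,
    loso_cv,
    metrics_report,
    model_config,
    overall_metrics,
    per_class_metrics,
)
from mseienet.core_io import ValidationError, zscore_normalize
from mseienet.evaluation import round_half_up

# published multiclass confusion matrix (competition data, 4 MI tasks)
MULTICLASS_CM = ConfusionMatrix(
    np.array([
        [242, 8, 6, 3],
        [4, 247, 4, 4],
        [4, 4, 248, 3],
        [6, 7, 6, 240],
    ]),
    ("L", "R", "F", "T"),
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_enumerated_example(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_entries_sum_to_sample_count(self, rng):
        true = rng.integers(0, 4, 200)
        pred = rng.integers(0, 4, 200)
        assert confusion_matrix(true, pred, 4).total == 200

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            confusion_matrix([0, 5], [0, 1], 3)


class TestMetricFormulas:
    def test_multiclass_overall_accuracy_and_kappa(self):
        acc, mf1, kappa = overall_metrics(MULTICLASS_CM)
        # trace/total = 977/1036 = 94.3050...%, i.e. the published 94.30 to
        # within one unit in the last printed digit
        assert acc == pytest.approx(94.3050193, abs=1e-6)
        assert acc == pytest.approx(94.30, abs=0.0051)
        assert round_half_up(kappa) == 0.92
        # exact MF1 is 94.30; averaging the pre-rounded per-class F1 values
        # instead gives 94.31
        assert round_half_up(mf1) == 94.30
        report = metrics_report(MULTICLASS_CM)
        assert round_half_up(report.mf1_rounded_inputs) == 94.31

    def test_multiclass_tongue_row(self):
        pr, re, f1, _ = per_class_metrics(MULTICLASS_CM)
        t = MULTICLASS_CM.class_names.index("T")
        assert round_half_up(pr[t]) == 96.00
        assert round_half_up(re[t]) == 92.66
        assert round_half_up(f1[t]) == 94.30

    def test_all_diagonal_gives_perfect_metrics(self):
        cm = ConfusionMatrix(np.diag([5, 7, 3]), ("a", "b", "c"))
        pr, re, f1, _ = per_class_metrics(cm)
        np.testing.assert_allclose([pr, re, f1], 100.0)
        acc, mf1, kappa = overall_metrics(cm)
        assert acc == 100.0 and kappa == 1.0

    def test_chance_agreement_gives_zero_kappa(self):
        cm = ConfusionMatrix(np.full((2, 2), 25), ("a", "b"))
        acc, _, kappa = overall_metrics(cm)
        assert acc == 50.0
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_rows_proportional_to_column_totals_give_zero_kappa(self):
        # predictions independent of truth: rows proportional to (0.6, 0.4)
        cm = ConfusionMatrix(np.array([[30, 20], [6, 4]]), ("a", "b"))
        _, _, kappa = overall_metrics(cm)
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_metrics_invariant_under_class_permutation(self, rng):
        perm = np.array([2, 0, 3, 1])
        permuted = ConfusionMatrix(
            MULTICLASS_CM.counts[np.ix_(perm, perm)],
            tuple(MULTICLASS_CM.class_names[i] for i in perm),
        )
        a1 = overall_metrics(MULTICLASS_CM)
        a2 = overall_metrics(permuted)
        assert a1 == pytest.approx(a2)
        pr1, _, _, _ = per_class_metrics(MULTICLASS_CM)
        pr2, _, _, _ = per_class_metrics(permuted)
        np.testing.assert_allclose(pr1[perm], pr2)

    def test_undefined_class_flagged_and_reported_zero(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ("a", "b"))
        pr, re, f1, undefined = per_class_metrics(cm)
        assert undefined == ["b"]
        assert pr[1] == 0.0 and f1[1] == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ("a", "b"))
        with pytest.raises(ValueError, match="empty"):
            overall_metrics(cm)

    def test_rounding_is_half_up(self):
        assert round_half_up(94.305) == 94.31
        assert round_half_up(92.665) == 92.67
        assert round_half_up(0.915, 2) == 0.92


TINY_SYN = SyntheticConfig(n_trials_per_class=8, duration=0.8, effect_size=0.9,
                           seed=31)
TINY_AUG = AugmentationConfig(window_len=200, stride=10, noise_sd=0.005, seed=0)
TINY_TRAIN = TrainConfig(learning_rate=1e-3, batch_size=16, epochs=2, seed=0)


@pytest.fixture(scope="module")
def cv_result():
    trials = zscore_normalize(generate_mi_trials(TINY_SYN))
    return global_cv(
        trials, k=2, aug=TINY_AUG, model_cfg=model_config("tiny"),
        train_cfg=TINY_TRAIN, seed=0,
    ), trials


class TestCrossValidation:
    def test_folds_partition_trials(self, cv_result):
        result, trials = cv_result
        plan = result["plan"]
        assert plan.leakage_audit(trials.n_trials)
        assert result["leakage_audit_passed"]
        all_test = [i for fold in plan.fold_test_indices for i in fold]
        assert sorted(all_test) == list(range(trials.n_trials))

    def test_fold_test_sizes_stratified(self, cv_result):
        result, trials = cv_result
        for fold in result["plan"].fold_test_indices:
            labels = trials.labels[list(fold)]
            counts = np.bincount(labels, minlength=4)
            assert counts.max() - counts.min() <= 1

    def test_pooled_matrix_covers_every_trial(self, cv_result):
        result, trials = cv_result
        assert result["pooled_confusion"].total == trials.n_trials
        assert len(result["fold_reports"]) == 2

    def test_class_smaller_than_k_rejected(self):
        trials = zscore_normalize(generate_mi_trials(
            SyntheticConfig(n_trials_per_class=2, duration=0.8, seed=1)
        ))
        with pytest.raises(ValueError, match="fewer than k"):
            global_cv(trials, k=3, aug=None, model_cfg=model_config("tiny"),
                      train_cfg=TINY_TRAIN)

    def test_loso_reports_one_accuracy_per_subject(self):
        subjects = [
            zscore_normalize(generate_mi_trials(
                SyntheticConfig(n_trials_per_class=5, duration=0.8,
                                effect_size=0.9, seed=100 + s)
            ))
            for s in range(3)
        ]
        result = loso_cv(subjects, aug=None, model_cfg=model_config("tiny"),
                         train_cfg=TINY_TRAIN, seed=0, val_fraction=0.0)
        accs = result["per_subject_accuracy"]
        assert len(accs) == 3
        assert result["average_accuracy"] == pytest.approx(np.mean(accs))
        # each held-out confusion matrix covers exactly that subject's trials
        for cm, subject in zip(result["confusions"], subjects):
            assert cm.total == subject.n_trials

    def test_loso_needs_two_subjects(self):
        trials = zscore_normalize(generate_mi_trials(TINY_SYN))
        with pytest.raises(ValueError, match="2 subjects"):
            loso_cv([trials], None, model_config("tiny"), TINY_TRAIN)


class TestHyperparameterGrid:
    def test_full_grid_runs_every_combination(self):
        calls = []

        def fake_harness(lr, dropout):
            calls.append((lr, dropout))
            return 100.0 * lr + dropout

        lrs = [0.001, 0.0005, 0.0001]
        dropouts = [round(0.1 + 0.05 * i, 2) for i in range(9)]
        table = hyperparameter_grid(lrs, dropouts, fake_harness)
        assert table.shape == (3, 9)
        assert len(calls) == 27
        assert table[1, 2] == pytest.approx(100.0 * 0.0005 + dropouts[2])

    def test_single_point_grid_equals_plain_run(self):
        def harness(lr, dropout):
            return 42.0
        table = hyperparameter_grid([1e-3], [0.25], harness)
        assert table.shape == (1, 1)
        assert table[0, 0] == 42.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            hyperparameter_grid([], [0.1], lambda lr, d: 0.0)
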
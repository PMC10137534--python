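"""One-vs-rest accounting, metric identities, CV protocols, ROC."""

import inspect

import numpy as np
import pandas as pd
import pytest

from comaqeeg.evaluation import (
    ConfusionCounts,
    ModelSpec,
    compute_metrics,
    one_vs_rest_counts,
    roc_auc_ovr,
    run_kfold_cv,
    run_leave_one_patient_out,
)


def _ovr_enumeration_oracle(matrix, i):
    """Exhaustive cell-by-cell enumeration of TP/FN/FP/TN for class i."""
    tp = fn = fp = tn = 0
    for r in range(matrix.shape[0]):
        for c in range(matrix.shape[1]):
            v = int(matrix[r, c])
            if r == i and c == i:
                tp += v
            elif r == i:
                fn += v
            elif c == i:
                fp += v
            else:
                tn += v
    return tp, fn, fp, tn


class TestOneVsRest:
    def test_worked_three_class_example(self):
        m = np.array([[2, 1, 0], [0, 3, 0], [1, 0, 4]])
        conf = ConfusionCounts(m, ("a", "b", "c"))
        assert one_vs_rest_counts(conf, "a") == (2, 1, 1, 7)

    def test_matches_enumeration_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.integers(0, 9, (6, 6))
            conf = ConfusionCounts(m, tuple(range(3, 9)))
            for i, cls in enumerate(conf.classes):
                assert one_vs_rest_counts(conf, cls) == _ovr_enumeration_oracle(m, i)

    def test_counts_conserve_grand_total(self):
        m = np.random.default_rng(1).integers(0, 20, (6, 6))
        conf = ConfusionCounts(m, tuple(range(6)))
        for cls in conf.classes:
            assert sum(one_vs_rest_counts(conf, cls)) == m.sum()

    def test_perfect_diagonal_has_no_errors(self):
        conf = ConfusionCounts(np.diag([4, 5, 6]), ("x", "y", "z"))
        for cls in conf.classes:
            tp, fn, fp, tn = one_vs_rest_counts(conf, cls)
            assert fn == 0 and fp == 0

    def test_unknown_class_rejected(self):
        conf = ConfusionCounts(np.eye(2, dtype=int), ("a", "b"))
        with pytest.raises(ValueError):
            one_vs_rest_counts(conf, "zzz")


class TestMetrics:
    def test_perfect_classifier_all_ones(self):
        report = compute_metrics(ConfusionCounts(np.diag([5, 5, 5]), (1, 2, 3)))
        assert report.overall_accuracy == 1.0
        for m in ("sensitivity", "specificity", "precision", "f_score", "g_mean"):
            assert report.macro[m] == pytest.approx(1.0)

    def test_f1_is_harmonic_mean_and_gmean_identity(self):
        m = np.random.default_rng(2).integers(1, 15, (4, 4))
        report = compute_metrics(ConfusionCounts(m, tuple(range(4))), beta=1.0)
        for _, row in report.per_class.iterrows():
            hmean = 2 * row.precision * row.sensitivity / (row.precision + row.sensitivity)
            assert row.f_score == pytest.approx(hmean)
            assert row.g_mean**2 == pytest.approx(row.sensitivity * row.specificity)

    def test_metrics_match_per_instance_recount_oracle(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        conf = ConfusionCounts.from_predictions(y_true, y_pred, range(4))
        report = compute_metrics(conf)
        assert report.overall_accuracy == pytest.approx(float(np.mean(y_true == y_pred)))
        for cls in range(4):
            tp = int(np.sum((y_true == cls) & (y_pred == cls)))
            fn = int(np.sum((y_true == cls) & (y_pred != cls)))
            fp = int(np.sum((y_true != cls) & (y_pred == cls)))
            assert report.per_class.loc[cls, "sensitivity"] == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert report.per_class.loc[cls, "precision"] == pytest.approx(tp / (tp + fp))

    def test_zero_denominator_gives_nan_with_log(self, caplog):
        # class 1 never predicted -> precision undefined
        m = np.array([[3, 0], [2, 0]])
        with caplog.at_level("WARNING"):
            report = compute_metrics(ConfusionCounts(m, (0, 1)))
        assert np.isnan(report.per_class.loc[1, "precision"])
        assert "precision" in caplog.text


def _blobs(n_per_class=40, k_classes=6, d=8, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(k_classes):
        center = np.zeros(d)
        center[c % d] = sep * (1 + c // d)
        X.append(rng.normal(center, 1.0, (n_per_class, d)))
        y.append(np.full(n_per_class, c + 3))
    return np.vstack(X), np.concatenate(y)


class TestKfold:
    def test_default_fold_count_is_twenty(self):
        assert inspect.signature(run_kfold_cv).parameters["k"].default == 20

    @pytest.mark.parametrize("family", ["random_forest", "knn", "bagged_trees", "svm_cubic"])
    def test_separable_six_class_problem_solved(self, family):
        X, y = _blobs()
        _, report = run_kfold_cv(X, y, ModelSpec(family, seed=0), k=20, seed=0)
        assert report.overall_accuracy >= 0.95

    def test_deterministic_given_seed(self):
        X, y = _blobs(n_per_class=24)
        _, r1 = run_kfold_cv(X, y, ModelSpec("random_forest", seed=5), k=4, seed=5)
        _, r2 = run_kfold_cv(X, y, ModelSpec("random_forest", seed=5), k=4, seed=5)
        assert r1.overall_accuracy == r2.overall_accuracy
        pd.testing.assert_frame_equal(r1.per_class, r2.per_class)

    def test_undersized_class_error_names_it(self):
        X, y = _blobs(n_per_class=5)
        with pytest.raises(ValueError, match="only 5 instances"):
            run_kfold_cv(X, y, ModelSpec("knn"), k=20)

    def test_k_below_two_rejected(self):
        X, y = _blobs(n_per_class=10)
        with pytest.raises(ValueError):
            run_kfold_cv(X, y, ModelSpec("knn"), k=1)

    def test_leak_free_in_fold_balancing_runs(self):
        from comaqeeg.balancing import SmoteConfig

        X, y = _blobs(n_per_class=30)
        y[y == 8] = 7  # make one class larger -> imbalance
        _, report = run_kfold_cv(
            X, y, ModelSpec("knn"), k=3, seed=0, balance_in_fold=SmoteConfig(plan="auto")
        )
        assert report.overall_accuracy > 0.9


class TestLeaveOnePatientOut:
    def test_two_patient_nearest_neighbor_oracle(self):
        """With disjoint clouds and 1-NN, each patient is classified using
        only the other patient's data: labels are swapped."""
        rows = []
        for pid, gcs, center in (("A", 3, 0.0), ("B", 8, 10.0)):
            for i in range(4):
                rows.append({"patient_id": pid, "gcs": gcs, "f0": center + 0.1 * i, "f1": center})
        frame = pd.DataFrame(rows)
        out = run_leave_one_patient_out(frame, ["f0", "f1"], ModelSpec("knn"))
        assert len(out) == 2
        assert out.set_index("patient_id").loc["A", "y_pred"] == 8
        assert out.set_index("patient_id").loc["B", "y_pred"] == 3

    def test_fold_count_equals_patient_count_and_no_split(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(8):
            gcs = 3 + p % 3
            for s in range(3):
                rows.append(
                    {"patient_id": f"P{p}", "gcs": gcs,
                     "f0": gcs * 5 + rng.normal(), "f1": gcs * 5 + rng.normal()}
                )
        frame = pd.DataFrame(rows)
        out = run_leave_one_patient_out(frame, ["f0", "f1"], ModelSpec("knn"))
        assert len(out) == 8
        assert (out["n_segments"] == 3).all()

    def test_single_patient_rejected(self):
        frame = pd.DataFrame(
            {"patient_id": ["A"] * 3, "gcs": [3] * 3, "f0": [0.0, 0.1, 0.2]}
        )
        with pytest.raises(ValueError):
            run_leave_one_patient_out(frame, ["f0"], ModelSpec("knn"))


class TestRocAuc:
    def test_one_hot_scores_give_auc_one(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[y]
        auc = roc_auc_ovr(scores, y, (0, 1, 2))
        assert all(v == pytest.approx(1.0) for v in auc.values())

    def test_inverted_scores_give_auc_zero(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = 1.0 - np.eye(3)[y]
        auc = roc_auc_ovr(scores, y, (0, 1, 2))
        assert all(v == pytest.approx(0.0) for v in auc.values())

    def test_uniform_scores_near_chance(self):
        rng = np.random.default_rng(4)
        n = 10_000
        y = rng.integers(0, 2, n)
        scores = rng.uniform(size=(n, 2))
        auc = roc_auc_ovr(scores, y, (0, 1))
        assert auc[0] == pytest.approx(0.5, abs=0.02)

    def test_absent_class_gives_nan_with_log(self, caplog):
        y = np.zeros(10, dtype=int)
        scores = np.random.default_rng(0).uniform(size=(10, 2))
        with caplog.at_level("WARNING"):
            auc = roc_auc_ovr(scores, y, (0, 1))
        assert np.isnan(auc[1])
        assert "AUC undefined" in caplog.text
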
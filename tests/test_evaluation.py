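"""Splitting rules and the metric formulas, cross-checked against brute-force
arithmetic and scikit-learn."""

import numpy as np
import pandas as pd
import pytest

from hsichem import (
    ConfusionMatrix,
    SplitPlan,
    classification_metrics,
    confusion_matrix,
    kfold_indices,
    regression_metrics,
    stratified_split,
)
from hsichem.evaluation import quantification_report


class TestStratifiedSplit:
    def test_exact_division(self):
        labels = np.repeat("a", 30)
        parts = stratified_split(labels, SplitPlan((0.6, 0.2, 0.2), seed=0))
        assert [len(p) for p in parts] == [18, 6, 6]

    def test_disjoint_and_exhaustive(self):
        labels = np.array(["t"] * 87 + ["p"] * 30 + ["o"] * 30)
        parts = stratified_split(labels, SplitPlan(seed=1))
        allidx = np.concatenate(parts)
        assert len(allidx) == 147
        assert len(np.unique(allidx)) == 147

    def test_every_stratum_in_every_partition(self):
        labels = np.array(["t"] * 87 + ["p"] * 30 + ["o"] * 30)
        for part in stratified_split(labels, SplitPlan(seed=2)):
            assert set(labels[part]) == {"t", "p", "o"}

    def test_seed_reproducibility(self):
        labels = np.repeat(["a", "b"], 20)
        a = stratified_split(labels, SplitPlan(seed=5))
        b = stratified_split(labels, SplitPlan(seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_small_class_rejected(self):
        labels = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.raises(ValueError, match="partitions"):
            stratified_split(labels, SplitPlan((0.6, 0.2, 0.2), seed=0))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SplitPlan((0.5, 0.2))


class TestKFold:
    def test_equal_folds(self):
        folds = kfold_indices(10, 5, seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_partition(self):
        folds = kfold_indices(23, 5, seed=1)
        allidx = np.concatenate(folds)
        assert len(np.unique(allidx)) == 23
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_stratified_balance(self):
        labels = np.repeat(["a", "b"], 10)
        for fold in kfold_indices(20, 5, seed=0, stratify=labels):
            assert (labels[fold] == "a").sum() == 2

    def test_reproducible_and_validated(self):
        a = kfold_indices(12, 3, seed=9)
        b = kfold_indices(12, 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        with pytest.raises(ValueError):
            kfold_indices(3, 5)


class TestRegressionMetrics:
    def test_hand_computed_case(self):
        m = regression_metrics([1, 2, 3, 4], [1, 2, 3, 6])
        assert m.rmse == pytest.approx(1.0)
        assert m.r2 == pytest.approx(0.2)

    def test_perfect_prediction_rpd_error_path(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0
        with pytest.raises(ValueError, match="RPD undefined"):
            _ = m.rpd

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_rpd_times_rmse_equals_reference_sd(self, rng):
        y = rng.normal(size=50)
        pred = y + rng.normal(0, 0.3, 50)
        m = regression_metrics(y, pred)
        assert m.rpd * m.rmse == pytest.approx(y.std(), abs=1e-12)


def _brute_force_metrics(counts):
    """Eqs. for accuracy/precision/recall/F1/kappa computed class by class."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    k = counts.shape[0]
    accuracy = np.trace(counts) / total
    precisions, recalls, f1s = [], [], []
    for c in range(k):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r > 0 else 0.0)
    po = accuracy
    pe = sum(counts[c, :].sum() * counts[:, c].sum() for c in range(k)) / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return (accuracy, np.mean(precisions), np.mean(recalls), np.mean(f1s), kappa)


class TestClassificationMetrics:
    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), ("a", "b", "c"))
        m = classification_metrics(cm)
        assert (m.accuracy, m.precision, m.recall, m.f1, m.kappa) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_chance_agreement(self):
        m = classification_metrics(ConfusionMatrix([[5, 5], [5, 5]], ("a", "b")))
        assert m.accuracy == pytest.approx(0.5)
        assert m.kappa == pytest.approx(0.0)

    def test_three_class_case_matches_oracle(self):
        counts = [[8, 1, 1], [1, 8, 1], [0, 2, 8]]
        m = classification_metrics(ConfusionMatrix(counts, ("a", "b", "c")))
        acc, prec, rec, f1, kappa = _brute_force_metrics(counts)
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert m.precision == pytest.approx(prec, abs=1e-12)
        assert m.recall == pytest.approx(rec, abs=1e-12)
        assert m.f1 == pytest.approx(f1, abs=1e-12)
        assert m.kappa == pytest.approx(kappa, abs=1e-12)

    def test_random_matrices_match_oracle_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

        for _ in range(25):
            k = rng.integers(2, 5)
            counts = rng.integers(0, 12, size=(k, k))
            counts[np.diag_indices(k)] += 1        # nonempty rows
            m = classification_metrics(ConfusionMatrix(counts, tuple(range(k))))
            acc, prec, rec, f1, kappa = _brute_force_metrics(counts)
            assert m.precision == pytest.approx(prec, abs=1e-10)
            assert m.f1 == pytest.approx(f1, abs=1e-10)
            assert m.kappa == pytest.approx(kappa, abs=1e-10)
            # reconstruct label vectors for the sklearn cross-check
            y_true, y_pred = [], []
            for i in range(k):
                for j in range(k):
                    y_true += [i] * counts[i, j]
                    y_pred += [j] * counts[i, j]
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="macro", zero_division=0
            )
            assert m.precision == pytest.approx(p, abs=1e-10)
            assert m.recall == pytest.approx(r, abs=1e-10)
            assert m.f1 == pytest.approx(f, abs=1e-10)
            assert m.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-10
            )

    def test_kappa_invariant_under_class_permutation(self, rng):
        counts = rng.integers(0, 20, size=(4, 4))
        perm = rng.permutation(4)
        a = classification_metrics(ConfusionMatrix(counts, tuple(range(4))))
        b = classification_metrics(
            ConfusionMatrix(counts[np.ix_(perm, perm)], tuple(range(4)))
        )
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)

    def test_confusion_matrix_from_labels(self):
        cm = confusion_matrix(["a", "a", "b"], ["a", "b", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionMatrix(np.zeros((2, 2)), ("a", "b")))


def test_quantification_report_rows_match_metric_calls(rng):
    y = rng.normal(2, 0.5, 30)
    pred = y + rng.normal(0, 0.1, 30)
    cal = regression_metrics(y, pred)
    test = regression_metrics(y[:15], pred[:15] + 0.05)
    df = quantification_report([{
        "constituent": "norisoboldine", "model": "LSSVM", "selection": "CARS",
        "n_ews": 53, "calibration": cal, "prediction": test,
    }])
    row = df.iloc[0]
    assert row["Rc2"] == pytest.approx(round(cal.r2, 4))
    assert row["RMSEP"] == pytest.approx(round(test.rmse, 4))
    assert row["RPD"] == pytest.approx(round(test.rpd, 4))
    assert row["n_ews"] == 53
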
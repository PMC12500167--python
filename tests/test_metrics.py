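"""Tests for the fidelity metrics, cross-checked against independent
oracles (scipy's Wasserstein distance, sklearn's classification scores,
brute-force confusion matrices)."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import wasserstein_distance
from sklearn.metrics import precision_recall_fscore_support

from flowgen.metrics import (RBFConfig, batch_silhouette, classification_scores,
                             confusion_counts, correlation_discrepancy, mmd_rbf,
                             rmse, wasserstein_1d, wasserstein_mean)


class TestCorrelationDiscrepancy:
    def test_identical_inputs_zero(self, rng):
        A = rng.normal(size=(30, 5))
        assert correlation_discrepancy(A, A) == 0.0

    def test_opposite_perfect_correlations(self):
        t = np.linspace(0, 1, 10)
        A = np.column_stack([t, 2 * t + 1])       # correlation +1
        B = np.column_stack([t, -3 * t + 2])      # correlation -1
        # |R(A) - R(B)| = [[0, 2], [2, 0]], mean = 1
        assert np.isclose(correlation_discrepancy(A, B), 1.0)

    def test_row_permutation_invariance(self, rng):
        A = rng.normal(size=(40, 4))
        B = rng.normal(size=(25, 4))
        val = correlation_discrepancy(A, B)
        assert np.isclose(val, correlation_discrepancy(A[::-1], B[rng.permutation(25)]))

    def test_zero_variance_column_convention(self, rng):
        A = rng.normal(size=(20, 3))
        B = A.copy()
        B[:, 1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            val = correlation_discrepancy(A, B)
        assert np.isfinite(val)

    def test_column_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_discrepancy(rng.normal(size=(5, 2)), rng.normal(size=(5, 3)))


class TestWasserstein:
    def test_identical_zero_and_point_masses(self):
        A = np.array([[0.0], [1.0]])
        assert wasserstein_mean(A, A) == 0.0
        assert np.isclose(wasserstein_mean(np.array([[0.0]]), np.array([[1.0]])), 1.0)

    def test_shifted_pair_hand_example(self):
        a = np.array([[0.0], [1.0]])
        b = np.array([[1.0], [2.0]])
        assert np.isclose(wasserstein_mean(a, b), 1.0)

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 40))
            b = rng.normal(size=rng.integers(3, 40)) * 2 + 1
            assert np.isclose(wasserstein_1d(a, b), wasserstein_distance(a, b),
                              atol=1e-10)

    def test_agrees_with_sorted_quantile_oracle_equal_sizes(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        oracle = np.mean(np.abs(np.sort(a) - np.sort(b)))
        assert np.isclose(wasserstein_1d(a, b), oracle, atol=1e-10)

    def test_symmetry(self, rng):
        A = rng.normal(size=(20, 3))
        B = rng.normal(size=(15, 3))
        assert np.isclose(wasserstein_mean(A, B), wasserstein_mean(B, A))


class TestMMD:
    def test_identical_multisets_exactly_zero(self, rng):
        A = rng.normal(size=(25, 4))
        assert mmd_rbf(A, A.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_closed_form(self):
        delta, scale = 0.7, 0.5
        val = mmd_rbf(np.array([[0.0]]), np.array([[delta]]),
                      RBFConfig(scales=(scale,)))
        expected = 2.0 - 2.0 * np.exp(-delta ** 2 / (2 * scale ** 2))
        assert np.isclose(val, expected, atol=1e-12)

    def test_scale_averaging_is_arithmetic_mean(self, rng):
        A = rng.normal(size=(15, 3))
        B = rng.normal(size=(12, 3)) + 0.5
        combined = mmd_rbf(A, B, RBFConfig())
        singles = [mmd_rbf(A, B, RBFConfig(scales=(s,)))
                   for s in RBFConfig().scales]
        assert np.isclose(combined, np.mean(singles), atol=1e-12)

    def test_linear_kernel_option_and_validation(self, rng):
        A = rng.normal(size=(10, 2))
        assert np.isfinite(mmd_rbf(A, A + 1, RBFConfig(kernel="linear")))
        with pytest.raises(ValueError):
            RBFConfig(scales=(0.0,))


class TestClassificationScores:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a"])
        assert classification_scores(y, y) == (1.0, 1.0, 1.0, 1.0)

    def test_binary_hand_example(self):
        # TP=8, FP=2, FN=2, TN=8 for the positive class
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 8 + [0] * 2 + [0] * 8 + [1] * 2)
        prec, rec, f1, acc = classification_scores(y_true, y_pred)
        assert (prec, rec, f1, acc) == pytest.approx((0.8, 0.8, 0.8, 0.8))
        assert confusion_counts(y_true, y_pred, 1) == \
            {"TP": 8, "FP": 2, "FN": 2, "TN": 8}

    def test_absent_class_precision_zero(self):
        y_true = np.array(["a", "a", "b"])
        y_pred = np.array(["a", "a", "a"])   # class b never predicted
        prec, rec, f1, acc = classification_scores(y_true, y_pred)
        assert rec == pytest.approx(0.5)     # (1 + 0) / 2
        assert acc == pytest.approx(2 / 3)

    def test_matches_sklearn_macro_oracle(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        prec, rec, f1, _ = classification_scores(y_true, y_pred)
        s_prec, s_rec, s_f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        assert np.allclose((prec, rec, f1), (s_prec, s_rec, s_f1), atol=1e-12)

    def test_micro_and_weighted_match_sklearn(self, rng):
        y_true = rng.integers(0, 3, 120)
        y_pred = rng.integers(0, 3, 120)
        for mode in ("micro", "weighted"):
            prec, rec, f1, _ = classification_scores(y_true, y_pred, average=mode)
            oracle = precision_recall_fscore_support(
                y_true, y_pred, average=mode, zero_division=0)[:3]
            assert np.allclose((prec, rec, f1), oracle, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_scores(np.array([1]), np.array([1, 2]))


class TestBatchSilhouette:
    def test_well_mixed_batches_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        batches = np.array(["b1", "b2"] * 100)
        assert batch_silhouette(X, batches) > 0.9

    def test_separated_batches_near_zero(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-100, 0.1, size=(50, 3)),
                       rng.normal(100, 0.1, size=(50, 3))])
        batches = np.array(["b1"] * 50 + ["b2"] * 50)
        assert batch_silhouette(X, batches) < 0.1

    def test_label_renaming_invariance(self, rng):
        X = rng.normal(size=(60, 4))
        batches = rng.choice(["x", "y", "z"], 60)
        renamed = np.char.add("batch_", batches.astype(str))
        assert np.isclose(batch_silhouette(X, batches),
                          batch_silhouette(X, renamed))

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            batch_silhouette(rng.normal(size=(10, 2)), np.array(["b"] * 10))


class TestRMSE:
    def test_identical_zero_and_hand_example(self):
        A = np.array([0.0, 0.0])
        assert rmse(A, A) == 0.0
        assert np.isclose(rmse(A, np.array([3.0, 4.0])), np.sqrt(12.5))

    def test_symmetry(self, rng):
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert np.isclose(rmse(A, B), rmse(B, A))

    def test_keyed_tables_align_on_intersection(self):
        a = pd.Series({"p1|LR1": 1.0, "p2|LR2": 2.0, "p3|LR3": 5.0})
        b = pd.Series({"p1|LR1": 1.0, "p2|LR2": 4.0, "p9|LR9": 0.0})
        assert np.isclose(rmse(a, b), np.sqrt(2.0))   # over 2 shared keys

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rmse(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))
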
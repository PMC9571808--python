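"""LDA projection, CV-SVM classification, PLSR quantification, metrics."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from cyclenose import (
    compute_metrics,
    lda_fit_project,
    per_gas_concentration_classifier,
    plsr_quantify,
    svm_crossval,
)


def _blobs(n_classes=4, n_per_class=20, n_features=5, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_classes * n_per_class, n_features))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_classes):
        X[y == k, k % n_features] += sep * (k + 1)
    return X, y.astype(str)


class TestMetrics:
    def test_perfect_prediction(self):
        rmse, r2 = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r2 == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        t = np.array([0.0, 1.0, 2.0])
        rmse, r2 = compute_metrics(t, np.full(3, t.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        # SS_res = 9, SS_tot = 2 -> RMSE sqrt(3), R^2 = -3.5
        rmse, r2 = compute_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 5.0])
        assert rmse == pytest.approx(np.sqrt(3.0))
        assert r2 == pytest.approx(-3.5)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLDA:
    def test_four_classes_give_three_discriminants(self):
        X, y = _blobs(n_classes=4)
        scores = lda_fit_project(X, y)
        assert scores.n_functions == 3
        assert set(scores.scores.columns) == {"DF1", "DF2", "DF3", "label"}

    def test_identical_classes_share_centroid(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 4))
        third = rng.normal(size=(30, 4)) + 6.0
        X = np.vstack([base, base, third])
        y = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        scores = lda_fit_project(X, y)
        df = scores.scores
        dfs = [c for c in df.columns if c.startswith("DF")]
        ca = df[df.label == "a"][dfs].mean()
        cb = df[df.label == "b"][dfs].mean()
        np.testing.assert_allclose(ca.to_numpy(), cb.to_numpy(), atol=1e-6)

    def test_df1_carries_most_between_class_variance(self):
        X, y = _blobs(n_classes=3, sep=10.0)
        df = lda_fit_project(X, y).scores
        centroids = df.groupby("label")[["DF1", "DF2"]].mean()
        assert centroids["DF1"].var() > centroids["DF2"].var()


class TestSVMCrossval:
    def test_separable_data_classified_perfectly(self):
        X, y = _blobs()
        rep = svm_crossval(X, y, folds=10, seed=0)
        assert rep.accuracy_pct == 100.0
        assert np.all(rep.counts == np.diag(np.diag(rep.counts)))

    def test_row_percentages_sum_to_hundred(self):
        X, y = _blobs(sep=1.0)
        rep = svm_crossval(X, y, folds=5, seed=1)
        np.testing.assert_allclose(rep.row_percent.sum(axis=1), 100.0)
        assert rep.counts.sum() == len(y)

    def test_rerun_same_seed_identical(self):
        X, y = _blobs(sep=1.5)
        a = svm_crossval(X, y, folds=5, seed=7)
        b = svm_crossval(X, y, folds=5, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_permuted_labels_score_at_chance(self):
        """Accuracy of a 4-class balanced problem with shuffled labels stays
        near the 25% chance rate (median over 20 seeds within [15%, 35%])."""
        X, y = _blobs(n_per_class=25)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            yp = rng.permutation(y)
            accs.append(svm_crossval(X, yp, folds=5, seed=seed).accuracy_pct)
        assert 15.0 <= np.median(accs) <= 35.0

    def test_accuracy_invariant_to_feature_permutation_and_scale(self):
        X, y = _blobs(sep=2.0)
        base = svm_crossval(X, y, folds=5, seed=3).accuracy_pct
        perm = np.random.default_rng(0).permutation(X.shape[1])
        scaled = X[:, perm] * np.array([3.0, 0.2, 11.0, 0.5, 7.0]) + 4.0
        assert svm_crossval(scaled, y, folds=5, seed=3).accuracy_pct == pytest.approx(
            base
        )

    def test_small_class_rejected(self):
        X, y = _blobs(n_per_class=4)
        with pytest.raises(ValueError):
            svm_crossval(X, y, folds=10)

    def test_linear_kernel_supported(self):
        X, y = _blobs()
        rep = svm_crossval(X, y, kernel="linear", folds=5, seed=0)
        assert rep.kernel == "linear"
        assert rep.accuracy_pct == 100.0


class TestConcentrationClassifier:
    def test_separated_levels_classified_perfectly(self):
        rng = np.random.default_rng(0)
        levels = np.repeat([250, 500, 1000, 1500, 2000, 2500, 3000], 10)
        X = levels[:, None] / 100.0 + rng.normal(scale=0.05, size=(70, 3))
        rep = per_gas_concentration_classifier(X, levels, folds=5, seed=0)
        assert rep.accuracy_pct == 100.0
        assert len(rep.classes) == 7
        assert rep.classes == sorted(rep.classes, key=float)

    def test_identical_level_distributions_score_at_chance(self):
        """Two levels drawn from one distribution: ~50% accuracy across seeds."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 3))
            levels = np.repeat([500.0, 2000.0], 20)
            accs.append(
                per_gas_concentration_classifier(X, levels, folds=5, seed=seed).accuracy_pct
            )
        assert 30.0 <= np.mean(accs) <= 70.0

    def test_single_level_rejected(self):
        X = np.zeros((20, 3))
        with pytest.raises(ValueError):
            per_gas_concentration_classifier(X, np.full(20, 500.0))


class TestPLSR:
    def test_noiseless_linear_target_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 6))
        y = X @ np.array([3.0, -2.0, 1.0, 0.5, 0.0, 4.0]) + 7.0
        rep = plsr_quantify(X, y, split_seed=0)
        assert rep.r2 >= 0.999
        assert rep.rmse_ppb < 1e-6 * np.std(y) + 1e-6

    def test_permuted_target_has_no_skill(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 6))
        y = X @ np.array([3.0, -2.0, 1.0, 0.5, 0.0, 4.0])
        r2s = []
        for seed in range(20):
            yp = np.random.default_rng(seed).permutation(y)
            r2s.append(plsr_quantify(X, yp, split_seed=seed).r2)
        assert np.median(r2s) <= 0.1

    def test_full_rank_pls_equals_ols_on_training_data(self):
        """With as many components as features, PLSR reproduces the ordinary
        least-squares fit (with intercept) on its training data."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        pls = PLSRegression(n_components=5, scale=False).fit(X, y)
        A = np.column_stack([X, np.ones(20)])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(
            np.ravel(pls.predict(X)), A @ coef, atol=1e-8
        )

    def test_excessive_components_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        with pytest.raises(ValueError):
            plsr_quantify(X, y, n_components=10)

    def test_report_partition_sizes(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        y = X[:, 0] * 5.0 + rng.normal(scale=0.1, size=50)
        rep = plsr_quantify(X, y, split_seed=1)
        assert rep.n_train == 40 and rep.n_test == 10
        assert rep.n_test == len(rep.true_ppb) == len(rep.predicted_ppb)
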
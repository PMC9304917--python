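"""PCA, NIPALS PLS-DA, diagnostics, and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poriascreen import latent
from poriascreen.latent import (
    ConfusionMatrix,
    auc_score,
    class_metrics,
    cross_val_press,
    evaluate_metrics,
    fit_pca,
    fit_plsda,
    permutation_test,
)


def separable_toy(n=30, seed=0):
    """Two well-separated Gaussian classes in 4 features."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4)) * 0.2
    y = (np.arange(n) % 2).astype(float)
    X[:, 0] += 3 * y
    return X, y


class TestPCA:
    def test_single_varying_column(self):
        X = np.zeros((10, 3))
        X[:, 1] = np.arange(10)
        m = fit_pca(X, 1)
        assert m.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 6))
        m = fit_pca(X, 6)
        assert m.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(m.explained_variance_fraction) <= 1e-12)

    def test_known_covariance_eigenstructure(self):
        # cov [[2,1],[1,2]] has eigenvalues 3 and 1 -> PC1 fraction 0.75
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = rng.standard_normal((20_000, 2)) @ L.T
        m = fit_pca(X, 2)
        assert m.explained_variance_fraction[0] == pytest.approx(0.75, abs=0.01)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        X = rng.standard_normal((25, 7))
        mine = fit_pca(X, 4)
        ref = sk.PCA(n_components=4).fit(X)
        assert np.allclose(
            mine.explained_variance_fraction, ref.explained_variance_ratio_, atol=1e-10
        )
        for k in range(4):  # loadings equal up to sign
            assert (
                pytest.approx(1.0, abs=1e-8)
                == abs(float(mine.loadings[:, k] @ ref.components_[k]))
            )

    def test_rank_error(self):
        X = np.zeros((5, 3))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError):
            fit_pca(X, 2)


class TestPLSDA:
    def test_separable_single_feature(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([0, 1, 0, 1, 0, 1], dtype=float)
        m = fit_plsda(X, y, 1)
        assert np.array_equal(m.predict_class(X), y.astype(int))

    def test_duplicated_columns_same_predictions(self):
        X, y = separable_toy()
        single = fit_plsda(X[:, :1], y, 1)
        doubled = fit_plsda(np.hstack([X[:, :1], X[:, :1]]), y, 1)
        assert np.allclose(
            single.predict_continuous(X[:, :1]),
            doubled.predict_continuous(np.hstack([X[:, :1], X[:, :1]])),
            atol=1e-10,
        )

    def test_scores_orthogonal(self):
        X, y = separable_toy(40, seed=3)
        m = fit_plsda(X, y, 4)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((20, 5))
            y = (np.random.default_rng(seed + 50).standard_normal(20) > 0).astype(float)
            m = fit_plsda(X, y, 5)
            Xc = X - X.mean(0)
            beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
            assert np.max(np.abs(m.predict_continuous(X) - (Xc @ beta + y.mean()))) < 1e-8

    def test_matches_sklearn_pls(self):
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        X, y = separable_toy(36, seed=5)
        mine = fit_plsda(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(
            mine.predict_continuous(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_errors(self):
        X, y = separable_toy()
        with pytest.raises(ValueError):
            fit_plsda(X, np.zeros_like(y), 1)
        with pytest.raises(ValueError):
            fit_plsda(X, y, 10)


class TestMetrics:
    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 3))
        beta = np.array([1.0, -2.0, 0.5])
        yc = X @ beta
        y = (yc > np.median(yc)).astype(float)
        # construct X so that a linear map reproduces y exactly
        X2 = np.column_stack([y, rng.standard_normal(20)])
        m = fit_plsda(X2, y, 2)
        met = evaluate_metrics(m, X2, y, folds=5)
        assert met.R2Y == pytest.approx(1.0, abs=1e-10)
        assert met.RMSEE == pytest.approx(0.0, abs=1e-10)

    def test_loo_q2_matches_press_oracle(self):
        X, y = separable_toy(14, seed=7)
        n = len(y)
        press, _ = cross_val_press(X, y, 2, folds=n)  # leave-one-out
        press_oracle = 0.0
        for i in range(n):
            keep = np.delete(np.arange(n), i)
            sub = fit_plsda(X[keep], y[keep], 2)
            press_oracle += float((y[i] - sub.predict_continuous(X[i : i + 1])[0]) ** 2)
        assert press == pytest.approx(press_oracle, rel=1e-10)

    def test_pure_noise_q2_nonpositive(self):
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 10))
            y = (np.arange(40) % 2).astype(float)
            m = fit_plsda(X, y, 2)
            met = evaluate_metrics(m, X, y, folds=5)
            q2s.append(met.Q2)
        assert np.median(q2s) < 0

    def test_auc_separated_scores(self):
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auc_score(y, s) == 1.0
        assert auc_score(y, -s) == 0.0
        assert auc_score(y, np.zeros(6)) == 0.5

    def test_fold_degeneracy_error(self):
        X = np.random.default_rng(8).standard_normal((8, 3))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        m = fit_plsda(X, y, 1)
        with pytest.raises(ValueError, match="stratify"):
            evaluate_metrics(m, X, y, folds=4)


class TestClassMetrics:
    def test_simple_ratios(self):
        cm = ConfusionMatrix(TP=3, FN=1, TN=5, FP=1)
        m = class_metrics(cm)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.8333, abs=5e-5)
        assert m.accuracy == pytest.approx(0.8)

    def test_single_positive(self):
        m = class_metrics(ConfusionMatrix(TP=1, FN=0, TN=0, FP=0))
        assert m.sensitivity == 1.0
        assert m.specificity is None  # undefined, not zero

    def test_33_sample_class_sensitivity(self):
        # one miss out of 33 -> 0.970 at three decimals
        m = class_metrics(ConfusionMatrix(TP=32, FN=1, TN=30, FP=0))
        assert round(m.sensitivity, 3) == 0.970

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_accuracy_identity_property(self, tp, tn, fp, fn):
        total = tp + tn + fp + fn
        m = class_metrics(ConfusionMatrix(tp, tn, fp, fn))
        if total == 0:
            assert m.accuracy is None
        else:
            assert m.accuracy == pytest.approx((tp + tn) / total)
            assert m.CCR_percent == pytest.approx(100 * (tp + tn) / total)


class TestPermutationTest:
    def test_informative_model_valid(self):
        X, y = separable_toy(40, seed=9)
        res = permutation_test(X, y, 2, n_perm=30, seed=0, folds=5)
        assert res.valid
        assert np.all(res.permuted_Q2 < res.original_Q2)
        assert res.Q2_intercept <= 0

    def test_anchor_reproduces_original(self):
        X, y = separable_toy(30, seed=10)
        res = permutation_test(X, y, 2, n_perm=5, seed=0, folds=5)
        base = fit_plsda(X, y, 2)
        met = evaluate_metrics(base, X, y, folds=5)
        assert res.original_Q2 == pytest.approx(met.Q2, rel=1e-12)
        assert res.original_R2Y == pytest.approx(met.R2Y, rel=1e-12)

    def test_null_calibration(self):
        # pure-noise X: the original Q2 should sit inside the permutation
        # distribution (no spurious validity) in nearly all runs
        inside = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((40, 5))
            y = (np.arange(40) % 2).astype(float)
            res = permutation_test(X, y, 2, n_perm=50, seed=seed, folds=5)
            lo, hi = np.percentile(res.permuted_Q2, [2.5, 97.5])
            if lo <= res.original_Q2 <= hi:
                inside += 1
        assert inside >= 0.9 * runs

    def test_nperm_error(self):
        X, y = separable_toy()
        with pytest.raises(ValueError):
            permutation_test(X, y, 1, n_perm=0, seed=0)
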
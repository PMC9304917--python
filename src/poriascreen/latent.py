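"""PCA and PLS-DA with the full chemometric diagnostic surface.

PLS-DA here is PLS1 regression on a 0/1 class coding (1 = discriminating
class), fitted by NIPALS with deflation, classified at a fixed 0.5 threshold.
Diagnostics follow the SIMCA conventions: R2Y on the training fit, RMSEE with
n - a - 1 degrees of freedom (a = number of latent variables), Q2 and RMSECV
from deterministic interleaved ("venetian blind") cross-validation that
refits the whole pipeline per fold, AUC from the rank statistic of the
continuous prediction, and the 200-iteration permutation test whose validity
rule is: every permuted Q2 below the original and a Q2-versus-correlation
regression intercept at or below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from poriascreen._seeds import stream


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray  # (p, k) right singular vectors
    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,)
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """SVD of the column-centered matrix; fraction k = sigma_k^2 / sum sigma^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    frac = s**2 / (s**2).sum()
    k = n_components
    return PCAModel(
        loadings=Vt[:k].T,
        scores=U[:, :k] * s[:k],
        explained_variance_fraction=frac[:k],
        mean=mean,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    n_lv: int
    W: np.ndarray  # (p, a) X-weights, unit norm
    P: np.ndarray  # (p, a) X-loadings
    T: np.ndarray  # (n, a) X-scores (training)
    q: np.ndarray  # (a,) y-loadings
    coef: np.ndarray  # (p,) regression vector on centered X
    x_mean: np.ndarray
    y_mean: float
    threshold: float = 0.5

    def predict_continuous(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_continuous(X) >= self.threshold).astype(int)


def fit_plsda(X: np.ndarray, y01: np.ndarray, n_lv: int) -> PLSDAModel:
    """NIPALS PLS1 on mean-centered X and 0/1 y.

    Components maximize covariance with the class coding; scores are mutually
    orthogonal by deflation. With n_lv = rank(X) the prediction reproduces
    ordinary least squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds rank {rank}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate component: zero X-y covariance")
        w /= nw
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = (t @ yd) / tt
        Xd = Xd - np.outer(t, p_a)
        yd = yd - t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        n_lv=n_lv, W=W, P=P, T=T, q=q, coef=coef, x_mean=x_mean, y_mean=y_mean
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ModelMetrics:
    R2Y: float
    Q2: float
    RMSEE: float
    RMSECV: float
    AUC: float
    n_lv: int


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(((yt == 1) & (yp == 1)).sum()),
            TN=int(((yt == 0) & (yp == 0)).sum()),
            FP=int(((yt == 0) & (yp == 1)).sum()),
            FN=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass
class ClassMetrics:
    """SEN/SPE/ACC plus per-class %NER and overall %CCR.

    A ratio with a zero denominator is reported as None (undefined), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    NER_percent: dict = field(default_factory=dict)
    CCR_percent: float | None = None


def class_metrics(c: ConfusionMatrix) -> ClassMetrics:
    """SEN = TP/(TP+FN); SPE = TN/(TN+FP); ACC = (TP+TN)/total.

    %NER per class = 100 * correctly classified / class total; %CCR = 100 *
    correctly classified / grand total.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    ner = {}
    pos = ratio(c.TP, c.TP + c.FN)
    neg = ratio(c.TN, c.TN + c.FP)
    if pos is not None:
        ner["positive"] = 100.0 * pos
    if neg is not None:
        ner["negative"] = 100.0 * neg
    return ClassMetrics(
        sensitivity=pos,
        specificity=neg,
        accuracy=ratio(c.TP + c.TN, c.total),
        NER_percent=ner,
        CCR_percent=None if c.total == 0 else 100.0 * (c.TP + c.TN) / c.total,
    )


def auc_score(y01: np.ndarray, y_score: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic."""
    y = np.asarray(y01).astype(int).ravel()
    s = np.asarray(y_score, dtype=float).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def venetian_blind_folds(n: int, folds: int) -> list[np.ndarray]:
    """Deterministic interleaved fold assignment: record i -> fold i mod folds."""
    idx = np.arange(n)
    return [idx[idx % folds == f] for f in range(folds)]


def cross_val_press(
    X: np.ndarray, y01: np.ndarray, n_lv: int, folds: int = 7
) -> tuple[float, np.ndarray]:
    """PRESS from interleaved CV refitting the full model per fold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    n = y.size
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n")
    yhat_cv = np.empty(n)
    for test_idx in venetian_blind_folds(n, folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(
                "a CV fold left a single class in training; stratify the data "
                "or change the fold count"
            )
        a = min(n_lv, int(np.linalg.matrix_rank(X[train_idx] - X[train_idx].mean(0))))
        sub = fit_plsda(X[train_idx], y[train_idx], a)
        yhat_cv[test_idx] = sub.predict_continuous(X[test_idx])
    press = float(((y - yhat_cv) ** 2).sum())
    return press, yhat_cv


def evaluate_metrics(
    model: PLSDAModel, X: np.ndarray, y01: np.ndarray, folds: int = 7
) -> ModelMetrics:
    """Training R2Y/RMSEE, cross-validated Q2/RMSECV, and rank AUC.

    R2Y = 1 - SSE/SSY on the training fit; RMSEE = sqrt(SSE / (n - a - 1));
    Q2 = 1 - PRESS/SSY and RMSECV = sqrt(PRESS / n) from interleaved CV.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    n = y.size
    a = model.n_lv
    yhat = model.predict_continuous(X)
    sse = float(((y - yhat) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    if ssy == 0:
        raise ValueError("y has no variance")
    df = n - a - 1
    if df <= 0:
        raise ValueError("too few records for RMSEE degrees of freedom")
    press, _ = cross_val_press(X, y, a, folds)
    return ModelMetrics(
        R2Y=1 - sse / ssy,
        Q2=1 - press / ssy,
        RMSEE=float(np.sqrt(sse / df)),
        RMSECV=float(np.sqrt(press / n)),
        AUC=auc_score(y, yhat),
        n_lv=a,
    )


def select_n_lv(
    X: np.ndarray, y01: np.ndarray, max_lv: int = 10, folds: int = 7,
    tol: float = 0.01,
) -> int:
    """Smallest LV count whose Q2 is within ``tol`` of the maximum over 1..max_lv."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    ssy = float(((y - y.mean()) ** 2).sum())
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    q2 = []
    for a in range(1, min(max_lv, rank) + 1):
        press, _ = cross_val_press(X, y, a, folds)
        q2.append(1 - press / ssy)
    q2 = np.array(q2)
    best = q2.max()
    return int(np.flatnonzero(q2 >= best - tol)[0]) + 1


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    n_permutations: int
    correlations: np.ndarray  # |corr(y_perm, y)| per permutation
    permuted_R2Y: np.ndarray
    permuted_Q2: np.ndarray
    original_R2Y: float
    original_Q2: float
    R2_intercept: float
    Q2_intercept: float
    valid: bool


def _line_intercept(x: np.ndarray, y: np.ndarray) -> float:
    """Intercept of the least-squares line through (x, y) at x = 0."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def permutation_test(
    X: np.ndarray,
    y01: np.ndarray,
    n_lv: int,
    n_perm: int = 200,
    seed: int = 0,
    folds: int = 7,
) -> PermutationResult:
    """Label-permutation robustness check of a PLS-DA model.

    For each permutation the labels are shuffled, the model refitted with the
    same LV count, and (|corr(y_perm, y)|, R2Y, Q2) recorded. Lines are fitted
    through the permuted points plus the unpermuted anchor at correlation 1;
    the model is declared valid when every permuted Q2 lies below the original
    and the Q2 line's intercept at correlation 0 is at or below zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    base = fit_plsda(X, y, n_lv)
    base_metrics = evaluate_metrics(base, X, y, folds)

    rng = stream(seed, "permutation-test")
    cors = np.empty(n_perm)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    ssy = float(((y - y.mean()) ** 2).sum())
    for i in range(n_perm):
        while True:
            yp = rng.permutation(y)
            try:
                m = fit_plsda(X, yp, n_lv)
                press, _ = cross_val_press(X, yp, n_lv, folds)
                break
            except ValueError:
                continue  # pathological shuffle (e.g. fold degeneracy); redraw
        yhat = m.predict_continuous(X)
        r2s[i] = 1 - float(((yp - yhat) ** 2).sum()) / ssy
        q2s[i] = 1 - press / ssy
        cors[i] = abs(float(np.corrcoef(yp, y)[0, 1]))

    xs = np.concatenate([cors, [1.0]])
    r2_int = _line_intercept(xs, np.concatenate([r2s, [base_metrics.R2Y]]))
    q2_int = _line_intercept(xs, np.concatenate([q2s, [base_metrics.Q2]]))
    valid = bool(np.all(q2s < base_metrics.Q2) and q2_int <= 0)
    return PermutationResult(
        n_permutations=n_perm,
        correlations=cors,
        permuted_R2Y=r2s,
        permuted_Q2=q2s,
        original_R2Y=base_metrics.R2Y,
        original_Q2=base_metrics.Q2,
        R2_intercept=r2_int,
        Q2_intercept=q2_int,
        valid=valid,
    )
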
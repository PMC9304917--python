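"""OPLS-DA on common-peak tables and VIP > 1 biomarker screening.

The orthogonal-projection model splits X-variation into a single predictive
component (correlated with the 0/1 class coding) and ``n_ortho`` components
orthogonal to it, so class-irrelevant variance no longer leaks into the
predictive scores. VIP (variable importance in projection) is computed from
the predictive component only — the usual "VIP_pred" convention for
OPLS-DA — and the conventional VIP > 1 rule screens candidate biomarker
peaks. Peak tables are unit-variance scaled by default since relative areas
span magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from poriascreen.latent import cross_val_press, venetian_blind_folds  # noqa: F401
from poriascreen.synth import PeakTable


@dataclass
class OPLSDAModel:
    w_pred: np.ndarray  # (p,) unit predictive weight
    t_pred: np.ndarray  # (n,) predictive scores (training)
    p_pred: np.ndarray  # (p,) predictive loading
    q: float  # y-loading
    W_ortho: np.ndarray  # (p, n_ortho)
    T_ortho: np.ndarray  # (n, n_ortho)
    P_ortho: np.ndarray  # (p, n_ortho)
    R2X: float
    R2Y: float
    Q2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    feature_labels: tuple | None = None

    @property
    def n_ortho(self) -> int:
        return self.W_ortho.shape[1]

    def _filter(self, X: np.ndarray) -> np.ndarray:
        """Remove the orthogonal components from new (scaled) data."""
        Xc = (np.atleast_2d(np.asarray(X, float)) - self.x_mean) / self.x_scale
        for k in range(self.n_ortho):
            t_o = Xc @ self.W_ortho[:, k]
            Xc = Xc - np.outer(t_o, self.P_ortho[:, k])
        return Xc

    def predict_continuous(self, X: np.ndarray) -> np.ndarray:
        return self._filter(X) @ self.w_pred * self.q + self.y_mean

    def predict_class(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_continuous(X) >= threshold).astype(int)

    def predictive_scores(self, X: np.ndarray) -> np.ndarray:
        return self._filter(X) @ self.w_pred


def _fit_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS decomposition of centered/scaled X against centered y."""
    w = Xc.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("zero X-y covariance; cannot extract a predictive weight")
    w = w / nw
    p_dim = Xc.shape[1]
    W_o = np.zeros((p_dim, n_ortho))
    T_o = np.zeros((Xc.shape[0], n_ortho))
    P_o = np.zeros((p_dim, n_ortho))
    Xd = Xc.copy()
    for k in range(n_ortho):
        t = Xd @ w
        p_vec = Xd.T @ t / (t @ t)
        w_o = p_vec - (w @ p_vec) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValueError(
                f"no orthogonal variation left at component {k + 1}"
            )
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, k], T_o[:, k], P_o[:, k] = w_o, t_o, p_o
    t = Xd @ w
    p_vec = Xd.T @ t / (t @ t)
    q = float((t @ yc) / (t @ t))
    return w, t, p_vec, q, W_o, T_o, P_o


def _prepare(X, y01, scale):
    if isinstance(X, PeakTable):
        labels: tuple | None = tuple(X.peak_labels)
        X = X.areas
    else:
        labels = None
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y01, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    mean = X.mean(axis=0)
    if scale == "uv":
        sd = X.std(axis=0, ddof=1)
    elif scale == "pareto":
        sd = np.sqrt(X.std(axis=0, ddof=1))
    elif scale == "none":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling {scale!r}")
    if np.any(sd == 0):
        raise ValueError("constant column cannot be variance-scaled")
    return X, y, mean, sd, labels


def fit_oplsda(
    X, y01: np.ndarray, n_ortho: int = 1, scale: str = "uv", folds: int = 7
) -> OPLSDAModel:
    """Fit OPLS-DA with one predictive and ``n_ortho`` orthogonal components.

    R2X is the cumulative X-variance captured by all components, R2Y the
    explained variance of the class coding, and Q2 comes from interleaved
    cross-validation re-running the entire procedure (scaling included) per
    fold. ``X`` may be a matrix or a ``PeakTable``.
    """
    X, y, mean, sd, labels = _prepare(X, y01, scale)
    Xc = (X - mean) / sd
    rank = int(np.linalg.matrix_rank(Xc))
    if n_ortho < 0 or n_ortho > rank - 1:
        raise ValueError(f"n_ortho={n_ortho} must be in [0, rank-1] with rank {rank}")
    yc = y - y.mean()
    w, t, p_vec, q, W_o, T_o, P_o = _fit_core(Xc, yc, n_ortho)

    ssx = float((Xc**2).sum())
    captured = float((np.outer(t, p_vec) ** 2).sum()) + sum(
        float((np.outer(T_o[:, k], P_o[:, k]) ** 2).sum()) for k in range(n_ortho)
    )
    yhat = t * q
    ssy = float((yc**2).sum())
    r2y = 1 - float(((yc - yhat) ** 2).sum()) / ssy

    # cross-validated Q2 over the full pipeline
    n = y.size
    yhat_cv = np.empty(n)
    for test_idx in venetian_blind_folds(n, folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("a CV fold left a single class in training")
        sub = _fit_plain(X[train_idx], y[train_idx], n_ortho, scale)
        yhat_cv[test_idx] = sub.predict_continuous(X[test_idx])
    q2 = 1 - float(((y - yhat_cv) ** 2).sum()) / ssy

    return OPLSDAModel(
        w_pred=w, t_pred=t, p_pred=p_vec, q=q,
        W_ortho=W_o, T_ortho=T_o, P_ortho=P_o,
        R2X=captured / ssx, R2Y=r2y, Q2=q2,
        x_mean=mean, x_scale=sd, y_mean=float(y.mean()),
        feature_labels=labels,
    )


def _fit_plain(X, y, n_ortho, scale) -> OPLSDAModel:
    """Fit without CV (used inside the CV loop)."""
    X, y, mean, sd, labels = _prepare(X, y, scale)
    Xc = (X - mean) / sd
    yc = y - y.mean()
    w, t, p_vec, q, W_o, T_o, P_o = _fit_core(Xc, yc, n_ortho)
    return OPLSDAModel(
        w_pred=w, t_pred=t, p_pred=p_vec, q=q,
        W_ortho=W_o, T_ortho=T_o, P_ortho=P_o,
        R2X=np.nan, R2Y=np.nan, Q2=np.nan,
        x_mean=mean, x_scale=sd, y_mean=float(y.mean()),
        feature_labels=labels,
    )


def choose_n_ortho(
    X, y01: np.ndarray, max_ortho: int = 5, scale: str = "uv",
    folds: int = 7, tol: float = 0.01,
) -> int:
    """Increase orthogonal components while cross-validated Q2 improves by > tol."""
    best = fit_oplsda(X, y01, 0, scale, folds).Q2
    chosen = 0
    for k in range(1, max_ortho + 1):
        try:
            q2 = fit_oplsda(X, y01, k, scale, folds).Q2
        except ValueError:
            break
        if q2 > best + tol:
            best, chosen = q2, k
        else:
            break
    return chosen


@dataclass
class VIPResult:
    """Per-variable VIP scores; sum of squares equals the variable count."""

    vip: np.ndarray
    labels: tuple
    threshold: float = 1.0

    @property
    def selected(self) -> list:
        return screen_biomarkers(self, self.threshold)


def vip_scores(m: OPLSDAModel) -> VIPResult:
    """VIP from the predictive component: VIP_j = sqrt(p) * |w_j| / ||w||."""
    w = m.w_pred
    p = w.size
    vip = np.sqrt(p) * np.abs(w) / np.linalg.norm(w)
    labels = m.feature_labels if m.feature_labels is not None else tuple(range(p))
    return VIPResult(vip=vip, labels=tuple(labels))


def screen_biomarkers(v: VIPResult, threshold: float = 1.0) -> list:
    """Variable labels with VIP strictly above threshold, descending by VIP."""
    order = np.argsort(-v.vip, kind="stable")
    return [v.labels[i] for i in order if v.vip[i] > threshold]
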
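"""Univariate partial least squares (PLS1) with a full component path.

All three wavelength selectors score candidate band subsets by RMSECV of
a PLS1 model, so this engine is optimised for that workload: one NIPALS
pass yields the regression coefficient vector for *every* component count
1..A simultaneously, making a K-fold RMSECV sweep over component counts
cost K single fits rather than K*A.

Conventions: predictors are centred and (by default) scaled to unit
variance on the training fold; the response is centred.  Component counts
in cross-validation are capped at ``min(max_components, n_train - 1,
n_features)``; ties in RMSECV are broken toward fewer components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PLS1", "kfold_indices", "rmsecv", "RMSECVResult"]

_TOL = 1e-12


class PLS1(BaseEstimator, RegressorMixin):
    """PLS1 regression exposing the whole component path.

    Attributes (after fit)
    ----------------------
    coef_path_ : (n_features, A) coefficients on the original predictor
        scale, column a-1 for a components.
    intercept_path_ : (A,) matching intercepts.
    coef_, intercept_ : the full-A (last) model.
    n_components_ : number of components actually extracted (may be fewer
        than requested when the predictor space is exhausted).
    """

    def __init__(self, n_components: int = 10, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have different sample counts")
        if np.ptp(y) == 0:
            raise ValueError("constant response: PLS1 problem is undefined")
        A = int(min(self.n_components, max(n - 1, 1), p))
        self.x_mean_ = X.mean(axis=0)
        sx = X.std(axis=0, ddof=1) if n > 1 else np.ones(p)
        sx = np.where(sx > 0, sx, 1.0)
        self.x_std_ = sx if self.scale else np.ones(p)
        self.y_mean_ = y.mean()

        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        a = 0
        for a in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < _TOL:
                break
            w /= nw
            t = Xc @ w
            tt = t @ t
            if tt < _TOL:
                break
            pa = Xc.T @ t / tt
            qa = yc @ t / tt
            Xc -= np.outer(t, pa)
            yc -= qa * t
            W[:, a], P[:, a], q[a] = w, pa, qa
            a += 1
        n_comp = max(a, 1)
        W, P, q = W[:, :n_comp], P[:, :n_comp], q[:n_comp]

        # R = W (P'W)^{-1} built incrementally; B path = cumsum(q_a r_a)
        R = np.zeros_like(W)
        for j in range(n_comp):
            r = W[:, j].copy()
            for b in range(j):
                r -= (P[:, b] @ W[:, j]) * R[:, b]
            R[:, j] = r
        B = np.cumsum(R * q, axis=1)          # scaled-space coefficients
        self.coef_path_ = B / self.x_std_[:, None]
        self.intercept_path_ = self.y_mean_ - self.x_mean_ @ self.coef_path_
        self.coef_ = self.coef_path_[:, -1]
        self.intercept_ = float(self.intercept_path_[-1])
        self.n_components_ = n_comp
        return self

    def predict(self, X, n_components: int | None = None):
        X = np.asarray(X, dtype=float)
        if n_components is None:
            return X @ self.coef_ + self.intercept_
        a = min(n_components, self.n_components_) - 1
        return X @ self.coef_path_[:, a] + self.intercept_path_[a]

    def predict_path(self, X):
        """Predictions for every component count: (n_samples, A)."""
        X = np.asarray(X, dtype=float)
        return X @ self.coef_path_ + self.intercept_path_


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic K-fold partition: a seeded permutation split into
    ``folds`` nearly equal contiguous blocks."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


@dataclass(frozen=True)
class RMSECVResult:
    """RMSECV over the PLS component path for one band subset."""

    rmsecv: float            #: minimum over component counts
    n_components: int        #: argmin (ties -> fewer components)
    per_component: np.ndarray  #: RMSECV for 1..A components


def rmsecv(X, y, max_components: int = 10, folds: int = 5,
           seed: int = 0, scale: bool = True) -> RMSECVResult:
    """K-fold RMSECV of PLS1, minimised over the component count.

    The fold assignment is a deterministic function of ``(seed, n,
    folds)``; the same inputs and seed always give the same value.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("constant response: RMSECV undefined")
    fold_idx = kfold_indices(n, folds, seed)
    A = int(min(max_components, min(n - len(f) for f in fold_idx) - 1, p))
    A = max(A, 1)
    sq_err = np.zeros(A)
    for test in fold_idx:
        train = np.setdiff1d(np.arange(n), test)
        model = PLS1(n_components=A, scale=scale).fit(X[train], y[train])
        pred = model.predict_path(X[test])          # (n_test, n_comp)
        a_fit = pred.shape[1]
        err = (pred - y[test, None]) ** 2
        sq_err[:a_fit] += err.sum(axis=0)
        if a_fit < A:                # path exhausted early: reuse last model
            sq_err[a_fit:] += err[:, -1].sum()
    per_comp = np.sqrt(sq_err / n)
    best = int(np.argmin(per_comp))          # first minimum: fewer components
    return RMSECVResult(rmsecv=float(per_comp[best]), n_components=best + 1,
                        per_component=per_comp)
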
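"""Partial least squares core (PLS1, NIPALS) and cross-validated RMSE.

This is the engine under every wavelength selector: CARS ranks bands by the
magnitude of PLS regression coefficients, random frog scores candidate subsets
by cross-validated PLS error, and subset quality is reported as RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "pls_fit", "pls_predict", "rmsecv", "kfold_split"]


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # (bands, a) NIPALS weights
    x_loadings: np.ndarray     # (bands, a)
    y_loadings: np.ndarray     # (a,)
    coef: np.ndarray           # (bands,) regression vector on centered X
    x_scores: np.ndarray       # (samples, a) training scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS deflation.

    ``n_components`` is capped at min(samples-1, bands); raises on degenerate
    (zero-variance) y.  Successive score vectors are mutually orthogonal by
    construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; PLS undefined")
    a = int(min(n_components, n - 1, p))
    if a < 1:
        raise ValueError("need at least one latent variable")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    T = np.zeros((n, a))
    for i in range(a):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:          # residual X carries no covariance with y
            a = i
            break
        w /= nw
        t = E @ w
        tt = t @ t
        if tt < 1e-14:
            a = i
            break
        p_i = E.T @ t / tt
        q_i = (t @ f) / tt
        E = E - np.outer(t, p_i)
        f = f - q_i * t
        W[:, i], P[:, i], q[i], T[:, i] = w, p_i, q_i, t
    if a == 0:
        raise ValueError("no usable latent variable (X orthogonal to y)")
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=a, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, coef=coef, x_scores=T,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def kfold_split(n: int, k: int, seed: int | None = 0) -> list[np.ndarray]:
    """Seeded near-equal folds (sizes differ by at most 1)."""
    if k > n:
        raise ValueError("more folds than samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    idx = np.arange(n)
    if seed is not None:
        np.random.default_rng(seed).shuffle(idx)
    return [fold for fold in np.array_split(idx, k)]


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Root-mean-square of out-of-fold PLS prediction errors.

    Fold assignment is fixed by ``seed``; the component count is additionally
    capped by each training fold's size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    press = 0.0
    for test in kfold_split(n, folds, seed):
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        model = pls_fit(X[train], y[train], n_components)
        resid = y[test] - model.predict(X[test])
        press += float(resid @ resid)
    return float(np.sqrt(press / n))
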
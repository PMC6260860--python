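"""Negative-binomial GLM (log link, fixed dispersion) via Fisher scoring.

The NB2 parameterization is used throughout: Var(Y) = mu + alpha * mu^2.
Coefficients are on the natural-log scale; callers convert to log2.
"""

from __future__ import annotations

import numpy as np

_ETA_CLIP = 30.0  # exp(30) ~ 1e13; keeps separated designs finite


def nb_glm_fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
               alpha: float, max_iter: int = 100, tol: float = 1e-10):
    """Fit an NB GLM with log link and known dispersion ``alpha``.

    Returns ``(beta, cov)`` where ``cov`` is the inverse expected Fisher
    information at the optimum. For boundary cases (a design cell with all
    zeros) the linear predictor is clipped, which bounds the estimate.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    # start from a regularized log-linear fit
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)          # E[-d2l/deta2]
        score = X.T @ ((y - mu) / (1.0 + alpha * mu))
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), score)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if norm < tol:
            break
    beta = np.clip(beta, -_ETA_CLIP, _ETA_CLIP)
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.pinv(info)
    return beta, cov


def wald_test(beta: np.ndarray, cov: np.ndarray, index: int):
    """Two-sided Wald test for one coefficient; returns (estimate, se, z, p)."""
    from scipy import stats

    est = beta[index]
    var = cov[index, index]
    if var <= 0 or not np.isfinite(var):
        return est, np.inf, 0.0, 1.0
    se = float(np.sqrt(var))
    z = float(est / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(est), se, z, p
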
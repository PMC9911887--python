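"""Spectral (eigendecomposition-based) REML for single-kinship mixed models.

Model: y = W a + g + e with g ~ N(0, sigma_g2 * K), e ~ N(0, sigma_e2 * I).
Writing delta = sigma_e2 / sigma_g2, V = sigma_g2 (K + delta I), the REML
log-likelihood profiles analytically over a and sigma_g2, leaving a
one-dimensional search over delta that is solved on a log grid followed by
Brent refinement. This is the standard trick used by EMMA-class mixed-model
association methods and keeps every variance-component fit O(n^3) once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

_LOG_DELTA_RANGE = (-10.0, 10.0)
_GRID_POINTS = 81


@dataclass
class SpectralREMLFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    log_reml: float
    eigvals: np.ndarray        # eigenvalues of K
    eigvecs: np.ndarray        # columns are eigenvectors of K
    beta: np.ndarray           # GLS fixed-effect estimates at the optimum


def _profile_quantities(y_t: np.ndarray, W_t: np.ndarray, s: np.ndarray, delta: float):
    d = s + delta
    w = 1.0 / d
    WtDW = W_t.T @ (W_t * w[:, None])
    WtDy = W_t.T @ (y_t * w)
    beta = np.linalg.solve(WtDW, WtDy)
    r = y_t - W_t @ beta
    rss = float(np.sum(r * r * w))
    return d, WtDW, beta, rss


def _log_reml(y_t: np.ndarray, W_t: np.ndarray, s: np.ndarray, delta: float) -> float:
    n, q = W_t.shape
    d, WtDW, _, rss = _profile_quantities(y_t, W_t, s, delta)
    nq = n - q
    sigma_g2 = rss / nq
    if sigma_g2 <= 0:
        return -np.inf
    sign, logdet_WtDW = np.linalg.slogdet(WtDW)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        nq * np.log(2.0 * np.pi * sigma_g2)
        + np.sum(np.log(d))
        + logdet_WtDW
        + nq
    )


def fit_spectral_reml(
    y: np.ndarray, W: np.ndarray, K: np.ndarray, *, eig: tuple[np.ndarray, np.ndarray] | None = None
) -> SpectralREMLFit:
    """REML estimates of (sigma_g2, sigma_e2) for y = Wa + g + e.

    Parameters
    ----------
    y : (n,) response
    W : (n, q) fixed-effect design (must include the intercept)
    K : (n, n) symmetric PSD covariance structure of g
    eig : optional precomputed (eigenvalues, eigenvectors) of K

    Notes
    -----
    K need not be full rank; zero eigenvalues are handled through delta.
    Slightly negative eigenvalues from round-off are clamped at 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = y.shape[0]
    if W.shape[0] != n:
        raise ValueError("W rows must match len(y)")
    if eig is None:
        s, U = np.linalg.eigh((K + K.T) / 2.0)
    else:
        s, U = eig
    s = np.clip(s, 0.0, None)
    y_t = U.T @ y
    W_t = U.T @ W

    grid = np.linspace(*_LOG_DELTA_RANGE, _GRID_POINTS)
    vals = np.array([_log_reml(y_t, W_t, s, float(np.exp(g))) for g in grid])
    i = int(np.nanargmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_log_reml(y_t, W_t, s, float(np.exp(ld))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if np.isfinite(res.fun) else float(grid[i])
    delta = float(np.exp(log_delta))

    _, _, beta, rss = _profile_quantities(y_t, W_t, s, delta)
    nq = n - W.shape[1]
    sigma_g2 = rss / nq
    sigma_e2 = delta * sigma_g2
    return SpectralREMLFit(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        delta=delta,
        log_reml=float(_log_reml(y_t, W_t, s, delta)),
        eigvals=s,
        eigvecs=U,
        beta=beta,
    )
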
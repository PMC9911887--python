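"""RR-BLUP genomic prediction with repeated-split cross-validation.

Ridge-regression BLUP treats every marker as a random effect with a
common variance:

    y = X b + M u + e,   u ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I)

The shrinkage ratio lambda = sigma_e^2 / sigma_u^2 is estimated by
spectral REML on the equivalent kinship model (K = M M'), after which
marker effects come from the mixed-model equations in their n x n form:

    u_hat = M' (M M' + lambda I)^{-1} (y - X b_hat)

Prediction accuracy is the Pearson correlation between predicted and
observed values on held-out genotypes, averaged over repeated random
80/20 splits (150 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_spectral_reml

log = logging.getLogger(__name__)


@dataclass
class RRBlupModel:
    marker_effects: np.ndarray
    beta: np.ndarray           # fixed-effect estimates (intercept first)
    lam: float                 # sigma_e^2 / sigma_u^2
    sigma_u2: float
    sigma_e2: float
    n_markers: int

    def predict(self, M: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        if M.shape[1] != self.n_markers:
            raise ValueError(
                f"marker matrix has {M.shape[1]} markers; model was trained on {self.n_markers}"
            )
        if X is None:
            X = np.ones((M.shape[0], 1))
        return X @ self.beta + M @ self.marker_effects


def fit_rrblup(
    y: np.ndarray,
    M: np.ndarray,
    X: np.ndarray | None = None,
    lam: float | None = None,
) -> RRBlupModel:
    """Fit RR-BLUP marker effects.

    Parameters
    ----------
    y : (n,) phenotype vector
    M : (n, m) marker dosages (no missing values; impute beforehand)
    X : optional fixed-effect design; defaults to an intercept column.
        Pass year dummies here for the joint two-year mode.
    lam : fix the shrinkage ratio instead of estimating it by REML
        (used by oracle tests and the infinite-shrinkage limit).
    """
    y = np.asarray(y, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    if y.shape[0] != n:
        raise ValueError("y length must match marker matrix rows")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype vector; nothing to fit")
    if X is None:
        X = np.ones((n, 1))

    K = M @ M.T
    if lam is None:
        fit = fit_spectral_reml(y, X, K)
        sigma_u2, sigma_e2 = fit.sigma_g2, fit.sigma_e2
        lam = fit.delta
    else:
        sigma_u2, sigma_e2 = float("nan"), float("nan")

    V = K + lam * np.eye(n)
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid = y - X @ beta
    u = M.T @ np.linalg.solve(V, resid)
    return RRBlupModel(
        marker_effects=u, beta=beta, lam=float(lam),
        sigma_u2=sigma_u2, sigma_e2=sigma_e2, n_markers=m,
    )


@dataclass
class CVResult:
    trait: str
    mode: str
    accuracies: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def iterations(self) -> int:
        return len(self.accuracies)


def _split(rng: np.random.Generator, n: int, train_frac: float):
    idx = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return idx[:n_train], idx[n_train:]


def cross_validate(
    y: np.ndarray | pd.Series,
    M: np.ndarray,
    train_frac: float = 0.8,
    iterations: int = 150,
    mode: str = "mean",
    seed: int = 0,
    trait: str = "",
    year: np.ndarray | None = None,
) -> CVResult:
    """Repeated random-split cross-validation of RR-BLUP accuracy.

    For single-vector modes (per-year phenotypes or the across-year
    mean) y holds one value per genotype and rows of M are genotypes.
    For mode="joint", y is plot/entry-level with a parallel year label
    array; M rows repeat per genotype-year record, year enters as a
    fixed factor, and splitting is done on unique genotypes (rows
    sharing a genotype stay on the same side of the split).

    Iterations whose test fold has constant observed values are
    resampled (with a log entry).
    """
    y = np.asarray(y, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for cross-validation")
    rng = np.random.default_rng(seed)

    if mode == "joint":
        if year is None:
            raise ValueError("mode='joint' requires a year label array")
        year = np.asarray(year)
        years = np.unique(year)
        X = np.column_stack(
            [np.ones(n)] + [(year == yr).astype(float) for yr in years[1:]]
        )
        groups = _row_groups(M)
    else:
        X = np.ones((n, 1))
        groups = np.arange(n)

    uniq = np.unique(groups)
    accs = []
    attempts = 0
    while len(accs) < iterations and attempts < 20 * iterations:
        attempts += 1
        tr_g, te_g = _split(rng, len(uniq), train_frac)
        tr = np.isin(groups, uniq[tr_g])
        te = ~tr
        if np.ptp(y[te]) == 0 or np.ptp(y[tr]) == 0:
            log.info("cross_validate: constant fold, resampled")
            continue
        model = fit_rrblup(y[tr], M[tr], X[tr])
        pred = model.predict(M[te], X[te])
        if np.ptp(pred) == 0:
            accs.append(0.0)
            continue
        accs.append(stats.pearsonr(pred, y[te])[0])
    if len(accs) < iterations:
        raise RuntimeError("cross-validation could not assemble enough valid folds")
    return CVResult(trait=trait, mode=mode, accuracies=np.array(accs), seed=seed)


def _row_groups(M: np.ndarray) -> np.ndarray:
    """Group identical marker rows (same genotype repeated across years)."""
    _, inverse = np.unique(M, axis=0, return_inverse=True)
    return inverse


def compare_modes(
    pheno_by_year: dict,
    M: np.ndarray,
    iterations: int = 150,
    train_frac: float = 0.8,
    seed: int = 0,
    trait: str = "",
) -> dict[str, CVResult]:
    """Year-wise input-mode comparison with shared folds per iteration.

    pheno_by_year maps year -> (n_genotypes,) phenotype vector aligned
    with M's rows. Evaluates each single year, the joint model (year as
    fixed factor) and the across-year mean, reusing the same genotype
    split in every mode so the comparison is paired.
    """
    years = sorted(pheno_by_year)
    Y = np.column_stack([np.asarray(pheno_by_year[yr], dtype=float) for yr in years])
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    accs: dict[str, list] = {f"year{yr}": [] for yr in years}
    accs["joint"] = []
    accs["mean"] = []

    y_mean = Y.mean(axis=1)
    y_joint = Y.T.ravel()
    year_lab = np.repeat(years, n)
    M_joint = np.tile(M, (len(years), 1))
    X_joint = np.column_stack(
        [np.ones(len(y_joint))] + [(year_lab == yr).astype(float) for yr in years[1:]]
    )

    it = 0
    attempts = 0
    while it < iterations and attempts < 20 * iterations:
        attempts += 1
        tr, te = _split(rng, n, train_frac)
        vectors = [Y[:, j] for j in range(len(years))] + [y_mean]
        if any(np.ptp(v[te]) == 0 or np.ptp(v[tr]) == 0 for v in vectors):
            continue
        it += 1
        for j, yr in enumerate(years):
            model = fit_rrblup(Y[tr, j], M[tr])
            pred = model.predict(M[te])
            accs[f"year{yr}"].append(stats.pearsonr(pred, Y[te, j])[0])
        model = fit_rrblup(y_mean[tr], M[tr])
        pred = model.predict(M[te])
        accs["mean"].append(stats.pearsonr(pred, y_mean[te])[0])
        tr_j = np.concatenate([tr + n * j for j in range(len(years))])
        te_j = np.concatenate([te + n * j for j in range(len(years))])
        model = fit_rrblup(y_joint[tr_j], M_joint[tr_j], X_joint[tr_j])
        pred = model.predict(M_joint[te_j], X_joint[te_j])
        accs["joint"].append(stats.pearsonr(pred, y_joint[te_j])[0])
    if it < iterations:
        raise RuntimeError("compare_modes could not assemble enough valid folds")
    return {
        mode: CVResult(trait=trait, mode=mode, accuracies=np.array(a), seed=seed)
        for mode, a in accs.items()
    }
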
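"""Loaf-volume prediction from simpler quality traits.

Bread loaf volume (LV) is expensive to phenotype; ordinary least
squares on up to three cheaper quality traits (protein content,
sedimentation volume, mixing time, alveograph parameters, ...) gives a
screening-grade predictor. Models are fitted on genotype BLUPs and
validated by repeated random 50/50 train/test splits; the reported
cross-validation score is the mean Pearson correlation between
predicted and observed LV on the held-out half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

#: condition number above which a collinearity warning is emitted
_COND_WARN = 1e8


@dataclass
class RegressionModel:
    response: str
    predictors: tuple
    intercept: float
    coefficients: dict
    r2_multiple: float
    r2_adjusted: float
    residual_se: float
    p_value_overall: float
    n_obs: int
    cv_correlation: float | None = None
    cv_correlations: np.ndarray | None = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame) -> pd.Series:
        pred = pd.Series(self.intercept, index=table.index)
        for name, b in self.coefficients.items():
            pred = pred + b * table[name]
        return pred


def parse_equation(equation: str) -> tuple[str, list[str]]:
    """Parse 'LV ~ FS + W + P/L' into (response, predictors)."""
    if "~" not in equation:
        raise ValueError("equation must look like 'LV ~ FS + W + P/L'")
    lhs, rhs = equation.split("~", 1)
    preds = [p.strip() for p in rhs.split("+") if p.strip()]
    return lhs.strip(), preds


def fit_lv_equation(
    blups: pd.DataFrame, predictors: list[str], response: str = "LV"
) -> RegressionModel:
    """OLS fit of response on up to three predictor traits."""
    if not 1 <= len(predictors) <= 3:
        raise ValueError("between 1 and 3 predictors are supported")
    cols = [response] + list(predictors)
    missing = [c for c in cols if c not in blups.columns]
    if missing:
        raise ValueError(f"traits absent from the BLUP table: {missing}")
    data = blups[cols].dropna()
    p = len(predictors)
    if len(data) < p + 2:
        raise ValueError(f"need at least {p + 2} genotypes to fit {p} predictors")
    X = sm.add_constant(data[list(predictors)].to_numpy())
    cond = np.linalg.cond(X)
    if cond > _COND_WARN:
        warnings.warn(
            f"predictor design is near-collinear (condition number {cond:.3g})",
            stacklevel=2,
        )
    fit = sm.OLS(data[response].to_numpy(), X).fit()
    return RegressionModel(
        response=response,
        predictors=tuple(predictors),
        intercept=float(fit.params[0]),
        coefficients={name: float(b) for name, b in zip(predictors, fit.params[1:])},
        r2_multiple=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        residual_se=float(np.sqrt(fit.mse_resid)),
        p_value_overall=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
    )


def validate_split(
    blups: pd.DataFrame,
    predictors: list[str],
    response: str = "LV",
    train_frac: float = 0.5,
    iterations: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """Repeated random-split validation of an LV equation.

    Each iteration refits the OLS model on a random train_frac share of
    genotypes and correlates predictions with observed response values
    on the rest. Iterations with a constant held-out response are
    skipped and logged; the returned array holds one correlation per
    completed iteration.
    """
    data = blups[[response] + list(predictors)].dropna()
    n = len(data)
    rng = np.random.default_rng(seed)
    cors = []
    attempts = 0
    while len(cors) < iterations and attempts < 20 * iterations:
        attempts += 1
        idx = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train = data.iloc[idx[:n_train]]
        test = data.iloc[idx[n_train:]]
        if test[response].std() == 0:
            log.info("validate_split: constant held-out response, iteration skipped")
            continue
        model = fit_lv_equation(train, predictors, response)
        pred = model.predict(test)
        if pred.std() == 0:
            cors.append(0.0)
            continue
        cors.append(stats.pearsonr(pred, test[response])[0])
    return np.asarray(cors)


def fit_and_validate(
    blups: pd.DataFrame,
    equation: str,
    iterations: int = 150,
    seed: int = 0,
    train_frac: float = 0.5,
) -> RegressionModel:
    """Fit an equation string and attach its cross-validation score."""
    response, predictors = parse_equation(equation)
    model = fit_lv_equation(blups, predictors, response)
    cors = validate_split(
        blups, predictors, response, train_frac=train_frac, iterations=iterations, seed=seed
    )
    model.cv_correlations = cors
    model.cv_correlation = float(np.mean(cors)) if len(cors) else float("nan")
    return model


def equation_report(models: list[RegressionModel]) -> pd.DataFrame:
    """Table mirroring the standard prediction-equation summary columns."""
    rows = [
        {
            "equation": f"{m.response}~" + "+".join(m.predictors),
            "multiple_r2": round(m.r2_multiple, 2),
            "adjusted_r2": round(m.r2_adjusted, 2),
            "residual_se": round(m.residual_se, 2),
            "p_value": m.p_value_overall,
            "cv_r": round(m.cv_correlation, 2) if m.cv_correlation is not None else "",
        }
        for m in models
    ]
    return pd.DataFrame(rows)
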
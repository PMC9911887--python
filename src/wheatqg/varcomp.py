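"""Multi-year variance components, heritability, BLUPs and correlations.

The plot-level model is

    y_ijk = mu + year_j + g_i + (gy)_ij + eps_ijk

with year fixed and genotype (g), genotype-by-year (gy) and the plot
residual (eps) random. Year is fixed because the target of inference is
the genotype BLUP and the entry-mean heritability; the residual then
measures within-trial plot error. In an unreplicated augmented design
(r=1) the residual is identified only through the replicated check
genotypes, so the fit refuses designs with no replicated cell.

REML estimation is delegated to statsmodels MixedLM (random intercept
per genotype plus a year-within-genotype variance component); BLUPs are
computed from Henderson's mixed-model equations at the REML estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .simulate import PlotPhenotypes


@dataclass
class VarianceComponents:
    trait: str
    vg: float
    vge: float
    ve: float
    e: int      # number of years
    r: float    # replicates per year (geometric mean over genotype-year cells)

    def __post_init__(self) -> None:
        self.vg = max(float(self.vg), 0.0)
        self.vge = max(float(self.vge), 0.0)
        self.ve = max(float(self.ve), 0.0)
        if self.e < 1 or self.r < 1:
            raise ValueError("design constants e and r must be >= 1")


@dataclass
class TraitSummary:
    trait: str
    mean: float
    sd: float
    cv: float          # percent; NaN when the trait mean is 0
    h2: float
    share_g: float     # percent of (vg + vge + ve)
    share_ge: float
    share_e: float


def _trait_frame(pheno: PlotPhenotypes, trait: str) -> pd.DataFrame:
    df = pheno.data[pheno.data["trait"] == trait]
    if df.empty:
        raise ValueError(f"trait {trait!r} not present in the phenotype table")
    return df.copy()


def _design_constants(df: pd.DataFrame) -> tuple[int, float]:
    e = df["year"].nunique()
    counts = df.groupby(["genotype", "year"]).size()
    r = float(np.exp(np.log(counts).mean()))
    return e, r


def fit_varcomp(pheno: PlotPhenotypes, trait: str) -> VarianceComponents:
    """REML variance components for one trait.

    Raises
    ------
    ValueError
        If fewer than 2 years or genotypes are present, or if no
        genotype-year cell is replicated (sigma_ge^2 and sigma_e^2 are then
        confounded and the model is unidentifiable).
    """
    df = _trait_frame(pheno, trait)
    if df["year"].nunique() < 2:
        raise ValueError(
            f"trait {trait}: at least 2 years are required to separate "
            "genotype-by-year variance from genotype variance"
        )
    if df["genotype"].nunique() < 2:
        raise ValueError(f"trait {trait}: at least 2 genotypes required")
    cell_sizes = df.groupby(["genotype", "year"]).size()
    if (cell_sizes < 2).all():
        raise ValueError(
            f"trait {trait}: no replicated genotype-year cell; "
            "sigma_ge^2 and sigma_e^2 are confounded (augmented designs need "
            "replicated checks)"
        )
    e, r = _design_constants(df)

    # degenerate (noise-free) designs break the numerical optimizer; peel
    # off exactly-zero components first
    tol = 1e-10 * max(float(df["value"].var(ddof=0)), 1.0)
    cell = df.groupby(["genotype", "year"])["value"]
    within_cell = float((df["value"] - cell.transform("mean")).pow(2).mean())
    if within_cell <= tol:
        means = cell.mean().unstack()
        adj = means - means.mean(axis=0)
        within_geno = float(adj.sub(adj.mean(axis=1), axis=0).pow(2).to_numpy().mean())
        if within_geno <= tol:
            vg = float(adj.mean(axis=1).var(ddof=1))
            return VarianceComponents(trait=trait, vg=vg, vge=0.0, ve=0.0, e=e, r=r)
        flat = means.stack().rename("value").reset_index()
        flat["year"] = flat["year"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM.from_formula(
                "value ~ C(year)", groups="genotype", re_formula="1", data=flat
            ).fit(reml=True, method="lbfgs", maxiter=500)
        return VarianceComponents(
            trait=trait, vg=float(np.asarray(fit.cov_re)[0, 0]),
            vge=float(fit.scale), ve=0.0, e=e, r=r,
        )

    df = df.assign(year=df["year"].astype(str))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "value ~ C(year)",
            groups="genotype",
            re_formula="1",
            vc_formula={"gy": "0 + C(year)"},
            data=df,
        )
        fit = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=500)
            except Exception:
                continue
            if fit.converged:
                break
        if fit is None:
            raise RuntimeError(f"trait {trait}: REML did not converge")
    vg = float(np.asarray(fit.cov_re)[0, 0])
    vge = float(np.asarray(fit.vcomp)[0]) if len(fit.vcomp) else 0.0
    ve = float(fit.scale)
    return VarianceComponents(trait=trait, vg=vg, vge=vge, ve=ve, e=e, r=r)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    h2 = vg / (vg + vge/e + ve/(r*e)); the G-by-year variance is averaged
    over e years and the plot residual over r*e plots per entry.
    """
    denom = vc.vg + vc.vge / vc.e + vc.ve / (vc.r * vc.e)
    if denom <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return vc.vg / denom


def variance_shares(vc: VarianceComponents) -> tuple[float, float, float]:
    """Percent of total (vg + vge + ve) variance per component."""
    total = vc.vg + vc.vge + vc.ve
    if total <= 0:
        raise ValueError("all variance components are zero")
    return (100.0 * vc.vg / total, 100.0 * vc.vge / total, 100.0 * vc.ve / total)


def trait_summary(pheno: PlotPhenotypes, vc: VarianceComponents) -> TraitSummary:
    """Mean/SD/CV on genotype-mean data plus component shares."""
    df = _trait_frame(pheno, vc.trait)
    means = df.groupby("genotype")["value"].mean()
    mean = float(means.mean())
    sd = float(means.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    sg, sge, se = variance_shares(vc)
    return TraitSummary(
        trait=vc.trait, mean=mean, sd=sd, cv=cv, h2=heritability(vc),
        share_g=sg, share_ge=sge, share_e=se,
    )


def cv_percent(sd: float, mean: float) -> float:
    """Coefficient of variation in percent: 100*sd/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def compute_blups(
    pheno: PlotPhenotypes, trait: str, vc: VarianceComponents | None = None
) -> pd.Series:
    """Genotype BLUPs for one trait, in trait units around the grand mean.

    Solves Henderson's mixed-model equations for the fixed year effects
    and the random genotype and genotype-by-year effects at the given
    (or freshly fitted) variance components. The returned value for
    genotype i is mu_hat + mean-year-effect + g_i, so shrinkage pulls
    entries toward the grand mean as vg/ve decreases.
    """
    df = _trait_frame(pheno, trait)
    if vc is None:
        vc = fit_varcomp(pheno, trait)
    genos = np.sort(df["genotype"].unique())
    years = np.sort(df["year"].unique())
    gi = pd.Categorical(df["genotype"], categories=genos).codes
    yi = pd.Categorical(df["year"], categories=years).codes
    n = len(df)
    ng, ny = len(genos), len(years)

    X = np.zeros((n, ny))  # intercept + year dummies (first year as baseline)
    X[:, 0] = 1.0
    for j in range(1, ny):
        X[yi == j, j] = 1.0
    y = df["value"].to_numpy(dtype=float)

    if vc.ve <= 0:
        ve = 1e-8 * max(vc.vg, vc.vge, 1.0)  # near-noiseless limit
    else:
        ve = vc.ve
    use_gy = vc.vge > 0 and ny >= 2

    Zg = np.zeros((n, ng))
    Zg[np.arange(n), gi] = 1.0
    blocks = [X, Zg]
    if use_gy:
        Zgy = np.zeros((n, ng * ny))
        Zgy[np.arange(n), gi * ny + yi] = 1.0
        blocks.append(Zgy)
    M = np.concatenate(blocks, axis=1)
    C = M.T @ M
    k = ny
    if vc.vg > 0:
        C[k : k + ng, k : k + ng] += np.eye(ng) * (ve / vc.vg)
    else:
        C[k : k + ng, k : k + ng] += np.eye(ng) * 1e12  # vg=0: shrink g to 0
    if use_gy:
        C[k + ng :, k + ng :] += np.eye(ng * ny) * (ve / vc.vge)
    sol = np.linalg.solve(C + 1e-10 * np.eye(C.shape[0]), M.T @ y)
    beta = sol[:ny]
    g = sol[ny : ny + ng]
    mu_grand = beta[0] + np.mean(np.concatenate([[0.0], beta[1:]]))
    return pd.Series(mu_grand + g, index=genos, name=trait)


def blup_table(pheno: PlotPhenotypes, traits: list[str] | None = None) -> pd.DataFrame:
    """Genotype-by-trait matrix of BLUPs."""
    traits = traits or pheno.traits()
    return pd.DataFrame({t: compute_blups(pheno, t) for t in traits})


def genotype_means(pheno: PlotPhenotypes, traits: list[str] | None = None) -> pd.DataFrame:
    """Raw genotype means per trait (the phenotypic-correlation input)."""
    traits = traits or pheno.traits()
    df = pheno.data[pheno.data["trait"].isin(traits)]
    return df.pivot_table(index="genotype", columns="trait", values="value", aggfunc="mean")[traits]


def correlations(values: pd.DataFrame, mode: str = "genetic") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    values is a genotype-by-trait matrix: BLUPs for mode="genetic", raw
    genotype means for mode="phenotypic" (the caller chooses the input;
    mode is recorded for bookkeeping only). Constant traits yield NaN
    entries. Returns (correlation matrix, p-value matrix).
    """
    if mode not in ("genetic", "phenotypic"):
        raise ValueError("mode must be 'genetic' or 'phenotypic'")
    cols = list(values.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = values[[cols[i], cols[j]]].dropna()
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def varcomp_report(pheno: PlotPhenotypes, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait components and summary, one row per trait."""
    traits = traits or pheno.traits()
    rows = []
    for t in traits:
        vc = fit_varcomp(pheno, t)
        s = trait_summary(pheno, vc)
        rows.append(
            {
                "trait": t, "vg": vc.vg, "vge": vc.vge, "ve": vc.ve,
                "mean": s.mean, "sd": s.sd, "cv": round(s.cv, 2),
                "h2": round(s.h2, 2),
                "share_g": round(s.share_g), "share_ge": round(s.share_ge),
                "share_e": round(s.share_e),
            }
        )
    return pd.DataFrame(rows).set_index("trait")
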
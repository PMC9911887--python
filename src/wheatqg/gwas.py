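"""Single-marker mixed-linear-model association scan (P3D).

Each trait's BLUP vector y is modelled as

    y = X beta + Z u + e,   Var(u) = sigma_a^2 K,   Var(e) = sigma_e^2 I

with X holding the intercept, the leading principal components of the
marker matrix (population-structure covariates) and the tested marker.
The null model's variance components are estimated once by spectral
REML (P3D: population parameters previously determined) and reused for
every marker, which reduces each marker test to a generalized
least-squares fit in the whitened coordinate system. Kinship is the
VanRaden-style centered cross-product scaled to mean diagonal 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._reml import fit_spectral_reml
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class StructureModel:
    """Population-structure correction: PC scores plus kinship matrix."""

    pca: np.ndarray      # (n_genotypes, n_pc) scores
    kinship: np.ndarray  # (n_genotypes, n_genotypes) symmetric PSD

    def __post_init__(self) -> None:
        K = self.kinship
        if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be square symmetric")
        if self.pca.shape[0] != K.shape[0]:
            raise ValueError("pca rows must match kinship dimension")


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop markers with too much missingness or too-rare minor alleles.

    Keeps markers with missing fraction <= max_missing and MAF >= min_maf
    (computed over non-missing calls).
    """
    keep = (geno.missing_fraction() <= max_missing) & (geno.maf() >= min_maf)
    n_kept = int(keep.sum())
    log.info("marker filter: %d of %d markers retained", n_kept, geno.n_markers)
    if n_kept == 0:
        raise ValueError("all markers removed by the missingness/MAF filter")
    return geno.subset_markers(keep)


def compute_structure(geno: GenotypeMatrix, n_pc: int = 3) -> StructureModel:
    """PCA scores and VanRaden-style kinship from mean-imputed dosages.

    K = W W' / c with W the column-centered dosage matrix and c chosen so
    that the mean diagonal of K is 1.
    """
    if n_pc >= geno.n_genotypes:
        raise ValueError("n_pc must be smaller than the number of genotypes")
    X = geno.imputed()
    W = X - X.mean(axis=0)
    K = W @ W.T
    c = np.trace(K) / K.shape[0]
    if c <= 0:
        raise ValueError("degenerate genotype matrix (no variation)")
    K = K / c
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    pca = U[:, :n_pc] * s[:n_pc]
    return StructureModel(pca=pca, kinship=K)


def _repair_psd(K: np.ndarray) -> np.ndarray:
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() >= -1e-10:
        return K
    log.warning("kinship not PSD (min eigenvalue %.3g); clamping", s.min())
    s = np.clip(s, 0.0, None)
    return (U * s) @ U.T


def mlm_scan(
    y: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    structure: StructureModel | None = None,
    *,
    method: str = "P3D",
) -> pd.DataFrame:
    """Scan every marker for association with y under the MLM.

    Parameters
    ----------
    y : BLUP (or phenotype) vector aligned to geno.genotype_ids. A pandas
        Series is reindexed by genotype id.
    structure : PCA + kinship; None means no correction (K = identity,
        no PC covariates), in which case the scan reduces to simple
        linear regression.

    Returns
    -------
    DataFrame with one row per tested marker: marker, chrom, cm, bp,
    p_value, neg_log10_p, effect (allelic substitution, minor allele),
    se, pve (% incremental R^2 on the whitened scale).
    """
    if method != "P3D":
        raise ValueError("only the P3D scan is implemented")
    if isinstance(y, pd.Series):
        y = y.reindex(geno.genotype_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = geno.n_genotypes
    if y.shape[0] != n:
        raise ValueError("y must align with geno.genotype_ids")

    if structure is None:
        W = np.ones((n, 1))
        K = np.eye(n)
    else:
        W = np.column_stack([np.ones(n), structure.pca])
        K = _repair_psd(structure.kinship)

    null = fit_spectral_reml(y, W, K)
    s, U = null.eigvals, null.eigvecs
    w = 1.0 / np.sqrt(s + null.delta)  # whitening weights

    yt = (U.T @ y) * w
    Wt = (U.T @ W) * w[:, None]
    X = geno.imputed()
    Xt = (U.T @ X) * w[:, None]

    # Frisch-Waugh-Lovell: residualize against the null fixed effects once
    Q, _ = np.linalg.qr(Wt)
    yr = yt - Q @ (Q.T @ yt)
    Xr = Xt - Q @ (Q.T @ Xt)

    q = W.shape[1]
    df_resid = n - q - 1
    rss0 = float(yr @ yr)
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    keep = xx > 1e-10 * max(xx.max(), 1.0)  # drop monomorphic / collinear markers
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.info("mlm_scan: skipped %d monomorphic markers", n_skipped)

    beta = np.where(keep, xy / np.where(keep, xx, 1.0), np.nan)
    ssr = beta**2 * xx
    rss1 = rss0 - ssr
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssr / (rss1 / df_resid)
        p = stats.f.sf(F, 1, df_resid)
        se = np.sqrt(rss1 / df_resid / np.where(keep, xx, 1.0))
        pve = 100.0 * ssr / rss0

    out = pd.DataFrame(
        {
            "marker": geno.marker_ids,
            "chrom": geno.chrom,
            "cm": geno.cm,
            "bp": geno.bp,
            "effect": beta,
            "se": se,
            "p_value": p,
            "pve": pve,
        }
    )
    out = out[keep].reset_index(drop=True)
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
    out.attrs["sigma_a2"] = null.sigma_g2
    out.attrs["sigma_e2"] = null.sigma_e2
    return out


def declare_mtas(
    scans: dict[str, pd.DataFrame] | pd.DataFrame,
    threshold_neg_log10: float = 3.0,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Declare marker-trait associations at -log10 p >= threshold.

    Benjamini-Hochberg FDR flags are computed per trait over the full
    scan and reported alongside (markers are not excluded by FDR).
    Markers significant for more than one trait are labelled multi-trait.
    """
    if isinstance(scans, pd.DataFrame):
        scans = {scans.attrs.get("trait", "trait"): scans}
    frames = []
    for trait, scan in scans.items():
        if scan.empty:
            continue
        scan = scan.copy()
        scan["trait"] = trait
        rej, qvals, _, _ = multipletests(scan["p_value"], alpha=fdr_alpha, method="fdr_bh")
        scan["fdr_q"] = qvals
        scan["fdr_significant"] = rej
        frames.append(scan[scan["neg_log10_p"] >= threshold_neg_log10])
    if not frames:
        return pd.DataFrame(
            columns=[
                "marker", "trait", "chrom", "cm", "bp", "effect", "se",
                "p_value", "pve", "neg_log10_p", "fdr_q", "fdr_significant",
                "multi_trait",
            ]
        )
    mta = pd.concat(frames, ignore_index=True)
    counts = mta.groupby("marker")["trait"].nunique()
    mta["multi_trait"] = mta["marker"].map(counts) > 1
    cols = [
        "marker", "trait", "chrom", "cm", "bp", "effect", "se",
        "p_value", "pve", "neg_log10_p", "fdr_q", "fdr_significant", "multi_trait",
    ]
    return mta[cols].sort_values(["chrom", "cm", "trait"]).reset_index(drop=True)
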
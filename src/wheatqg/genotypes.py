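"""Genotype container shared by the simulator, I/O layer and GWAS.

Dosages are minor-allele counts in {0, 1, 2}; missing calls are NaN.
Each marker carries a genetic (cM) and a physical (bp) position so that
association results can be expressed on the genetic map (for hotspot
calling) and on the assembly (for candidate-gene windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of genotypes.

    Attributes
    ----------
    dosages : (n_genotypes, n_markers) float array
        Minor-allele counts; NaN marks a missing call.
    genotype_ids : list of str
    marker_ids : list of str
    chrom : array of str, per marker
    cm : array of float, genetic position per marker (non-decreasing
        within a chromosome)
    bp : array of int, physical position per marker (1-based)
    alleles : list of (major, minor) base pairs per marker
    subpop : optional array of subpopulation labels per genotype
    """

    dosages: np.ndarray
    genotype_ids: list
    marker_ids: list
    chrom: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    alleles: list = field(default_factory=list)
    subpop: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.cm = np.asarray(self.cm, dtype=float)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        n, m = self.dosages.shape
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length does not match dosage rows")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.cm) == len(self.bp) == m):
            raise ValueError("marker annotation lengths do not match dosage columns")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        for c in np.unique(self.chrom):
            idx = self.chrom == c
            if np.any(np.diff(self.cm[idx]) < 0) or np.any(np.diff(self.bp[idx]) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing calls.

        Folded to [0, 0.5]; monomorphic markers return 0.
        """
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the marker mean."""
        X = self.dosages.copy()
        mu = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = mu[nan_c]
        return X

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            genotype_ids=list(self.genotype_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            chrom=self.chrom[keep],
            cm=self.cm[keep],
            bp=self.bp[keep],
            alleles=[self.alleles[i] for i in keep] if self.alleles else [],
            subpop=self.subpop,
        )

    def marker_frame(self) -> pd.DataFrame:
        """Marker annotation as a DataFrame (id, chrom, cM, bp)."""
        return pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chrom, "cm": self.cm, "bp": self.bp}
        )
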
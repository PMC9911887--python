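"""Bundled reference tables.

LANDRACE_TRAIT_TABLE holds published two-year trial summary statistics
for 15 quality and agronomic traits of a 170-accession Mediterranean
bread-wheat landrace panel: REML variance components (genotype,
genotype-by-year, residual), trait mean, standard deviation, coefficient
of variation (%), broad-sense heritability on an entry-mean basis
(e=2 years, r=1 replicate), and genomic-prediction accuracy. The table
serves as a fidelity check for the heritability/CV formulas and as a
source of realistic variance magnitudes for the simulator.
"""

from __future__ import annotations

import pandas as pd

#: columns: vg, vge, ve, mean, sd, cv, h2, gs_accuracy
_ROWS = {
    "GY": (0.87, 0.22, 1.19, 5.00, 0.87, 17.40, 0.56, 0.52),
    "TW": (0.52, 0.05, 3.25, 77.86, 1.28, 1.64, 0.24, -0.03),
    "TKW": (7.26, 6.25, 10.93, 43.73, 3.89, 8.91, 0.46, 0.46),
    "GH": (73.03, 64.12, 156.95, 42.47, 13.83, 32.57, 0.40, 0.16),
    "FY": (6.91, 0.46, 2.83, 63.92, 1.79, 2.80, 0.81, 0.33),
    "GP": (0.68, 0.42, 0.30, 12.88, 0.70, 5.46, 0.66, 0.55),
    "FP": (0.60, 0.36, 0.24, 10.55, 0.67, 6.30, 0.67, 0.53),
    "FS": (4.21, 0.94, 0.51, 10.02, 2.02, 20.15, 0.85, 0.48),
    "MT": (0.39, 0.00, 0.34, 1.94, 0.50, 25.64, 0.70, 0.59),
    "P": (605.47, 5.51, 499.08, 75.12, 19.91, 26.50, 0.71, 0.58),
    "W": (6290.46, 78.19, 1316.66, 144.55, 46.57, 32.21, 0.90, 0.64),
    "P/L": (0.45, 0.04, 0.31, 1.30, 0.44, 33.45, 0.72, 0.29),
    "LV": (4619.28, 1538.95, 1157.60, 644.01, 65.06, 10.10, 0.78, 0.43),
    "GFD": (6.30, 0.67, 5.73, 32.47, 3.00, 9.25, 0.67, 0.65),
    "GFR": (0.03, 0.0020, 0.06, 1.20, 0.23, 19.38, 0.44, 0.62),
}

LANDRACE_TRAIT_TABLE = pd.DataFrame.from_dict(
    _ROWS,
    orient="index",
    columns=["vg", "vge", "ve", "mean", "sd", "cv", "h2", "gs_accuracy"],
)
LANDRACE_TRAIT_TABLE.index.name = "trait"

#: trial design constants behind the published heritabilities
LANDRACE_N_YEARS = 2
LANDRACE_N_REPS = 1


def _corr_matrix() -> pd.DataFrame:
    traits = ["LV", "GP", "FS", "GH", "MT", "FY", "W", "P/L", "P"]
    import numpy as np

    R = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)

    def s(a, b, v):
        R.loc[a, b] = v
        R.loc[b, a] = v

    # loaf volume vs rheology: reported genetic correlations
    s("LV", "W", 0.74); s("LV", "MT", 0.77); s("LV", "FS", 0.79); s("LV", "P", 0.80)
    # protein is negatively related to LV and MT; weakly to gluten traits
    s("LV", "GP", -0.15); s("LV", "P/L", -0.35); s("LV", "GH", 0.15); s("LV", "FY", 0.20)
    s("GP", "FS", 0.31); s("GP", "GH", 0.15); s("GP", "MT", -0.15)
    s("GP", "W", -0.10); s("GP", "FY", -0.10); s("GP", "P", -0.10); s("GP", "P/L", 0.10)
    s("FS", "MT", 0.75); s("FS", "W", 0.55); s("FS", "P", 0.60)
    s("FS", "GH", 0.20); s("FS", "FY", 0.20); s("FS", "P/L", -0.05)
    # grain hardness vs milling and rheology: reported values
    s("GH", "FY", 0.46); s("GH", "MT", 0.45); s("GH", "P", 0.56); s("GH", "W", 0.61); s("GH", "P/L", 0.64)
    s("MT", "W", 0.80); s("MT", "P", 0.85); s("MT", "FY", 0.20); s("MT", "P/L", 0.05)
    s("FY", "W", 0.25); s("FY", "P", 0.25); s("FY", "P/L", 0.20)
    s("W", "P", 0.70); s("W", "P/L", 0.10)
    s("P", "P/L", 0.15)

    # project to the nearest well-conditioned correlation matrix
    w, v = np.linalg.eigh(R.to_numpy())
    w = np.clip(w, 5e-3, None)
    M = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    return pd.DataFrame(M, index=traits, columns=traits)


#: Genetic correlation structure among the quality traits relevant to
#: loaf-volume prediction. Reported panel correlations where available,
#: sign-consistent plausible values elsewhere, projected to positive
#: definiteness. Used to simulate trait panels with realistic covariance.
LANDRACE_TRAIT_CORRELATION = _corr_matrix()
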
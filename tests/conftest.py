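import numpy as np
import pandas as pd
import pytest

from wheatqg.genotypes import GenotypeMatrix
from wheatqg.simulate import (
    SimulationConfig,
    TraitSpec,
    simulate_genotypes,
    simulate_phenotypes,
)


def toy_genotypes(n=30, m=50, seed=0, chrom="1A", missing=0.0):
    """Small unstructured dosage matrix with sorted positions."""
    rng = np.random.default_rng(seed)
    D = rng.integers(0, 3, size=(n, m)).astype(float)
    if missing > 0:
        D[rng.uniform(size=D.shape) < missing] = np.nan
    return GenotypeMatrix(
        dosages=D,
        genotype_ids=[f"g{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        chrom=np.array([chrom] * m),
        cm=np.sort(rng.uniform(0, 100, m)),
        bp=np.sort(rng.choice(np.arange(1, 10**7), size=m, replace=False)),
    )


@pytest.fixture(scope="session")
def small_panel():
    """One shared 200x800 structured panel with a 50-QTL trait."""
    spec = [TraitSpec("T", vg=4.0, vge=1.0, ve=1.0, n_qtl=50, qtl_effect_share=0.5)]
    cfg = SimulationConfig(
        n_genotypes=200, n_markers=800, traits=spec, seed=42, n_reps=2, missing_rate=0.02
    )
    geno = simulate_genotypes(cfg)
    pheno = simulate_phenotypes(geno, cfg)
    return cfg, geno, pheno


def balanced_phenotypes(ng=6, e=2, r=2, vg=4.0, vge=1.0, ve=0.5, seed=1):
    """Fully balanced plot table with known generating components."""
    rng = np.random.default_rng(seed)
    g_eff = rng.standard_normal(ng) * np.sqrt(vg)
    gy_eff = rng.standard_normal((ng, e)) * np.sqrt(vge)
    year_eff = np.linspace(-0.5, 0.5, e)
    rows = []
    for i in range(ng):
        for j in range(e):
            for k in range(r):
                rows.append(
                    (
                        f"g{i}",
                        2016 + j,
                        k + 1,
                        "T",
                        10.0 + year_eff[j] + g_eff[i] + gy_eff[i, j] + rng.standard_normal() * np.sqrt(ve),
                    )
                )
    from wheatqg.simulate import PlotPhenotypes

    return PlotPhenotypes(
        data=pd.DataFrame(rows, columns=["genotype", "year", "rep", "trait", "value"])
    )
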
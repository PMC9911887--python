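"""Synthetic structured-panel generator.

Emulates a Mediterranean bread-wheat landrace diversity panel: three
genetic subpopulations plus admixed accessions, genotyped with a
medium-density SNP array, phenotyped for quantitative traits over two
years in an augmented field design with replicated checks.

Genotypes follow a Balding-Nichols construction: each marker has an
ancestral minor-allele frequency, and each subpopulation draws its own
frequency from a Beta distribution whose spread is governed by a
differentiation parameter (FST). Linkage disequilibrium is produced by
(a) positional autocorrelation of ancestral frequencies along the
genetic map and (b) a Gaussian-copula autoregressive process on each
haplotype, so that nearby markers are correlated within individuals and
the correlation decays with map distance. No coalescent is simulated.

Phenotypes decompose plot values as

    y_ijk = mean + year_j + g_i + (gy)_ij + eps_ijk

where the genotypic value g_i is a sparse-QTL marker term plus a
polygenic deviation, (gy) is the genotype-by-year interaction and eps
the plot residual. All random draws and the realized components are
returned as ground truth so parameter-recovery tests can score the
downstream estimators against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotypes import GenotypeMatrix

#: 21 hexaploid wheat chromosomes; desk-scale uniform map/assembly lengths.
WHEAT_CHROMOSOMES = [f"{i}{g}" for i in range(1, 8) for g in "ABD"]
DEFAULT_CHROM_CM = {c: 160.0 for c in WHEAT_CHROMOSOMES}
DEFAULT_CHROM_BP = {c: 600_000_000 for c in WHEAT_CHROMOSOMES}


@dataclass
class TraitSpec:
    """Specification of one simulated trait.

    vg, vge, ve are the genotypic, genotype-by-year and residual
    variances (trait units squared); n_qtl causal markers carry
    qtl_effect_share of vg, the rest is polygenic. correlated_with
    optionally names a previously simulated trait and a target genetic
    correlation with it.
    """

    name: str
    vg: float
    vge: float
    ve: float
    n_qtl: int = 0
    qtl_effect_share: float = 0.5
    mean: float = 0.0
    correlated_with: tuple[str, float] | None = None
    qtl_marker_indices: tuple | None = None  # fix causal markers instead of drawing them

    def __post_init__(self) -> None:
        if min(self.vg, self.vge, self.ve) < 0:
            raise ValueError(f"trait {self.name}: variances must be >= 0")
        if not 0.0 <= self.qtl_effect_share <= 1.0:
            raise ValueError(f"trait {self.name}: qtl_effect_share must be in [0, 1]")
        if self.n_qtl < 0:
            raise ValueError(f"trait {self.name}: n_qtl must be >= 0")


@dataclass
class SimulationConfig:
    """Panel-level simulation parameters.

    Defaults mirror the landrace study design: 170 genotypes in three
    subpopulations (plus admixed), two years, single-replicate augmented
    design with two checks replicated in every block.
    """

    n_genotypes: int = 170
    n_subpops: int = 3
    admixed_fraction: float = 26 / 170
    fst: float | tuple = 0.1
    n_markers: int = 5000
    chrom_lengths_cM: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_CM))
    chrom_lengths_bp: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_BP))
    maf_range: tuple = (0.05, 0.5)
    traits: list = field(default_factory=list)
    n_years: int = 2
    n_reps: int = 1
    check_genotypes: int = 2
    check_reps: int = 10
    missing_rate: float = 0.02
    ld_scale_cM: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not 0.0 <= self.admixed_fraction < 1.0:
            raise ValueError("admixed_fraction must be in [0, 1)")
        for name in ("n_genotypes", "n_subpops", "n_markers", "n_years", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if np.any(fst <= 0):
            raise ValueError("fst must be > 0 (use a small value for no differentiation)")
        if self.n_markers < len(self.chrom_lengths_cM):
            raise ValueError("n_markers must be at least the number of chromosomes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def fst_per_subpop(self) -> np.ndarray:
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if fst.size == 1:
            return np.full(self.n_subpops, float(fst[0]))
        if fst.size != self.n_subpops:
            raise ValueError("fst must be scalar or one value per subpopulation")
        return fst


@dataclass
class PhenotypeTruth:
    """Realized simulation truth for one trait."""

    qtl_markers: np.ndarray
    qtl_effects: np.ndarray
    g: pd.Series                 # genotypic values, indexed by genotype id
    gy: pd.DataFrame             # genotype x year interaction draws
    eps: pd.Series               # per-plot residuals, indexed like the plot table
    year_effects: dict


@dataclass
class PlotPhenotypes:
    """Plot-level phenotype records plus simulation truth (when simulated).

    data has columns (genotype, year, rep, trait, value); one row per plot
    per trait. truth maps trait name -> PhenotypeTruth.
    """

    data: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"genotype", "year", "rep", "trait", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table must have columns {sorted(required)}")
        if self.data.duplicated(["genotype", "year", "rep", "trait"]).any():
            raise ValueError("duplicate (genotype, year, rep, trait) records")
        if not np.isfinite(self.data["value"]).all():
            raise ValueError("phenotype values must be finite")

    def traits(self) -> list:
        return sorted(self.data["trait"].unique())

    def years(self) -> list:
        return sorted(self.data["year"].unique())


def _marker_positions(config: SimulationConfig, rng: np.random.Generator):
    chroms = list(config.chrom_lengths_cM)
    cm_len = np.array([config.chrom_lengths_cM[c] for c in chroms], dtype=float)
    # allocate markers proportionally to map length, at least one per chromosome
    raw = cm_len / cm_len.sum() * config.n_markers
    counts = np.maximum(np.floor(raw).astype(int), 1)
    while counts.sum() < config.n_markers:
        counts[int(np.argmax(raw - counts))] += 1
    while counts.sum() > config.n_markers:
        i = int(np.argmax(counts - raw))
        if counts[i] > 1:
            counts[i] -= 1
        else:  # pragma: no cover - degenerate tiny maps
            counts[int(np.argmax(counts))] -= 1
    chrom_arr, cm_arr, bp_arr = [], [], []
    for c, k in zip(chroms, counts):
        u = np.sort(rng.uniform(0.0, 1.0, size=k))
        chrom_arr.extend([c] * k)
        cm_arr.append(u * config.chrom_lengths_cM[c])
        bp_arr.append(np.maximum((u * config.chrom_lengths_bp[c]).astype(np.int64), 1))
    return np.array(chrom_arr), np.concatenate(cm_arr), np.concatenate(bp_arr)


def _ancestral_frequencies(chrom, cm, config: SimulationConfig, rng) -> np.ndarray:
    """AR(1) latent field along each chromosome mapped into maf_range."""
    z = np.empty(len(cm))
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        d = np.diff(cm[idx], prepend=cm[idx[0]])
        rho = np.exp(-d / config.ld_scale_cM)
        e = rng.standard_normal(len(idx))
        zz = np.empty(len(idx))
        zz[0] = e[0]
        for j in range(1, len(idx)):
            zz[j] = rho[j] * zz[j - 1] + np.sqrt(1.0 - rho[j] ** 2) * e[j]
        z[idx] = zz
    lo, hi = config.maf_range
    return lo + (hi - lo) * norm.cdf(z)


def _subpop_frequencies(p_anc: np.ndarray, fst: np.ndarray, rng) -> np.ndarray:
    """Balding-Nichols Beta draws, one frequency vector per subpopulation."""
    m = len(p_anc)
    out = np.empty((len(fst), m))
    for s, F in enumerate(fst):
        if F < 1e-6:
            out[s] = p_anc
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            out[s] = rng.beta(a, b)
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def _assign_subpops(config: SimulationConfig, rng):
    n = config.n_genotypes
    n_adm = int(round(config.admixed_fraction * n))
    n_core = n - n_adm
    base = np.repeat(np.arange(config.n_subpops), n_core // config.n_subpops)
    extra = np.arange(n_core - len(base)) % config.n_subpops
    labels = np.concatenate([base, extra]).astype(int)
    rng.shuffle(labels)
    return labels, n_adm


def _haplotype_copula(freq_ind: np.ndarray, chrom, cm, config: SimulationConfig, rng):
    """Draw two haplotypes per individual with AR(1) latent correlation.

    Returns the latent normals (kept so marker frequencies can be
    re-thresholded without redrawing LD structure) and the dosages.
    """
    n, m = freq_ind.shape
    z = np.empty((2 * n, m))
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        d = np.diff(cm[idx], prepend=cm[idx[0]])
        rho = np.exp(-d / config.ld_scale_cM)
        e = rng.standard_normal((2 * n, len(idx)))
        z[:, idx[0]] = e[:, 0]
        for j in range(1, len(idx)):
            z[:, idx[j]] = rho[j] * z[:, idx[j - 1]] + np.sqrt(1.0 - rho[j] ** 2) * e[:, j]
    return z


def _threshold_dosages(z: np.ndarray, freq_ind: np.ndarray) -> np.ndarray:
    thr = norm.ppf(freq_ind)  # (n, m)
    hap1 = (z[0::2] < thr).astype(float)
    hap2 = (z[1::2] < thr).astype(float)
    return hap1 + hap2


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate the structured SNP panel.

    The realized (pre-missingness) minor-allele frequency of every
    emitted marker is guaranteed to be at least maf_range[0]: markers
    drifting below the floor have their frequencies redrawn toward the
    upper part of the range (the latent haplotype field is reused, so LD
    structure is untouched).
    """
    rng = np.random.default_rng(config.seed)
    chrom, cm, bp = _marker_positions(config, rng)
    p_anc = _ancestral_frequencies(chrom, cm, config, rng)
    fst = config.fst_per_subpop()
    p_sub = _subpop_frequencies(p_anc, fst, rng)

    labels, n_adm = _assign_subpops(config, rng)
    n = config.n_genotypes
    freq_ind = np.empty((n, config.n_markers))
    n_core = n - n_adm
    freq_ind[:n_core] = p_sub[labels]
    subpop_names = np.array([f"SP{s + 1}" for s in labels], dtype=object)
    for i in range(n_adm):
        s1, s2 = rng.choice(config.n_subpops, size=2, replace=False)
        alpha = rng.uniform(0.2, 0.8)
        freq_ind[n_core + i] = alpha * p_sub[s1] + (1.0 - alpha) * p_sub[s2]
    subpop_names = np.concatenate([subpop_names, np.array(["ADMIXED"] * n_adm, dtype=object)])

    z = _haplotype_copula(freq_ind, chrom, cm, config, rng)
    dosages = _threshold_dosages(z, freq_ind)

    # enforce realized MAF floor by re-drawing frequencies of failing markers
    lo = config.maf_range[0]
    for _ in range(100):
        p_real = dosages.mean(axis=0) / 2.0
        maf_real = np.minimum(p_real, 1.0 - p_real)
        bad = np.nonzero(maf_real < lo)[0]
        if bad.size == 0:
            break
        p_new = rng.uniform(0.5 * (lo + config.maf_range[1]), config.maf_range[1], size=bad.size)
        p_sub_new = _subpop_frequencies(p_new, fst, rng)
        freq_ind[:n_core, bad] = p_sub_new[labels][:, :]
        for i in range(n_adm):
            freq_ind[n_core + i, bad] = p_sub_new[:, :].mean(axis=0)
        dosages[:, bad] = _threshold_dosages(z[:, bad], freq_ind[:, bad])
    else:  # pragma: no cover - rejection loop essentially always converges
        p_real = dosages.mean(axis=0) / 2.0
        bad = np.nonzero(np.minimum(p_real, 1 - p_real) < lo)[0]
        half = n // 2
        dosages[:half, bad] = 0.0
        dosages[half:, bad] = 1.0

    complete = dosages.copy()
    if config.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < config.missing_rate
        dosages = dosages.astype(float)
        dosages[mask] = np.nan

    # orient to the observed panel minor allele (what a file reader sees),
    # so write/read round trips are lossless
    with np.errstate(invalid="ignore"):
        flip = np.nanmean(dosages, axis=0) / 2.0 > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    complete[:, flip] = 2.0 - complete[:, flip]

    bases = ("A", "C", "G", "T")
    alleles = [tuple(rng.choice(bases, size=2, replace=False)) for _ in range(config.n_markers)]
    n_checks = min(config.check_genotypes, n)
    ids = [f"CHECK_{i + 1}" for i in range(n_checks)] + [
        f"L{i + 1:04d}" for i in range(n - n_checks)
    ]
    geno = GenotypeMatrix(
        dosages=dosages,
        genotype_ids=ids,
        marker_ids=[f"snp_{c}_{i}" for i, c in enumerate(chrom)],
        chrom=chrom,
        cm=cm,
        bp=bp,
        alleles=alleles,
        subpop=subpop_names,
    )
    geno._complete = complete  # pre-missingness dosages, used as phenotype truth
    return geno


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    """Center and rescale so the sample variance equals target exactly."""
    x = x - x.mean()
    v = x.var(ddof=1)
    if v <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def simulate_phenotypes(geno: GenotypeMatrix, config: SimulationConfig) -> PlotPhenotypes:
    """Simulate plot-level phenotypes for every configured trait."""
    if not config.traits:
        raise ValueError("config.traits is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    X = getattr(geno, "_complete", None)
    if X is None:
        X = geno.imputed()
    n = geno.n_genotypes
    ids = list(geno.genotype_ids)
    years = [2016 + j for j in range(config.n_years)]
    n_checks = min(config.check_genotypes, n)

    rows = []
    truth: dict[str, PhenotypeTruth] = {}
    g_store: dict[str, np.ndarray] = {}
    for spec in config.traits:
        if spec.n_qtl > geno.n_markers:
            raise ValueError(f"trait {spec.name}: n_qtl exceeds the number of markers")
        # genotypic value: sparse QTL part + polygenic deviation
        if spec.n_qtl > 0 and spec.qtl_effect_share > 0 and spec.vg > 0:
            if spec.qtl_marker_indices is not None:
                qtl = np.asarray(spec.qtl_marker_indices, dtype=int)
                if len(qtl) != spec.n_qtl:
                    raise ValueError(f"trait {spec.name}: qtl_marker_indices length must equal n_qtl")
            else:
                qtl = np.sort(rng.choice(geno.n_markers, size=spec.n_qtl, replace=False))
            beta = rng.standard_normal(spec.n_qtl)
            raw = X[:, qtl] @ beta
            sd = raw.std(ddof=1)
            scale = np.sqrt(spec.qtl_effect_share * spec.vg) / max(sd, 1e-12)
            beta = beta * scale
            g_qtl = (raw - raw.mean()) * scale
        else:
            qtl = np.array([], dtype=int)
            beta = np.array([])
            g_qtl = np.zeros(n)
        g_poly = _scale_to_variance(
            rng.standard_normal(n), (1.0 - spec.qtl_effect_share) * spec.vg
        ) if spec.vg > 0 else np.zeros(n)
        g = g_qtl + g_poly
        if spec.correlated_with is not None:
            other, rho = spec.correlated_with
            if other not in g_store:
                raise ValueError(f"trait {spec.name}: correlated_with references unknown trait {other}")
            if spec.vg > 0:
                base = _scale_to_variance(g_store[other], 1.0)
                own = _scale_to_variance(g, 1.0)
                g = np.sqrt(spec.vg) * (rho * base + np.sqrt(1.0 - rho**2) * own)
        g_store[spec.name] = g

        year_eff = {}
        if config.n_years == 1:
            year_eff[years[0]] = 0.0
        else:
            offs = np.linspace(-0.5, 0.5, config.n_years) * np.sqrt(spec.ve)
            for yr, o in zip(years, offs):
                year_eff[yr] = float(o)
        gy = rng.standard_normal((n, config.n_years)) * np.sqrt(spec.vge)
        gy_df = pd.DataFrame(gy, index=ids, columns=years)

        eps_idx = []
        eps_vals = []
        for i, gid in enumerate(ids):
            reps = config.check_reps if i < n_checks and config.check_reps > config.n_reps else config.n_reps
            for j, yr in enumerate(years):
                for k in range(reps):
                    e = rng.standard_normal() * np.sqrt(spec.ve)
                    val = spec.mean + year_eff[yr] + g[i] + gy[i, j] + e
                    rows.append((gid, yr, k + 1, spec.name, val))
                    eps_idx.append((gid, yr, k + 1))
                    eps_vals.append(e)
        truth[spec.name] = PhenotypeTruth(
            qtl_markers=qtl,
            qtl_effects=beta,
            g=pd.Series(g, index=ids),
            gy=gy_df,
            eps=pd.Series(eps_vals, index=pd.MultiIndex.from_tuples(eps_idx, names=["genotype", "year", "rep"])),
            year_effects=year_eff,
        )

    data = pd.DataFrame(rows, columns=["genotype", "year", "rep", "trait", "value"])
    return PlotPhenotypes(data=data, truth=truth)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_to_yaml(config: SimulationConfig) -> str:
    import yaml

    d = asdict(config)
    d["traits"] = [asdict(t) if isinstance(t, TraitSpec) else t for t in config.traits]
    return yaml.safe_dump(_to_plain(d), sort_keys=False)


def truth_table(pheno: PlotPhenotypes) -> pd.DataFrame:
    """Flatten QTL truth records into a TSV-ready table."""
    rows = []
    for trait, t in pheno.truth.items():
        for m, b in zip(t.qtl_markers, t.qtl_effects):
            rows.append({"trait": trait, "marker_index": int(m), "effect": float(b)})
    return pd.DataFrame(rows, columns=["trait", "marker_index", "effect"])
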
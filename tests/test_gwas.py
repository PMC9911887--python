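"""Marker filtering, structure correction and the P3D mixed-model scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from wheatqg._reml import fit_spectral_reml
from wheatqg.genotypes import GenotypeMatrix
from wheatqg.gwas import compute_structure, declare_mtas, filter_markers, mlm_scan
from wheatqg.simulate import SimulationConfig, TraitSpec, simulate_genotypes, simulate_phenotypes

from conftest import toy_genotypes


def make_geno(D, chrom=None):
    n, m = D.shape
    return GenotypeMatrix(
        dosages=np.asarray(D, dtype=float),
        genotype_ids=[f"g{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        chrom=np.array(chrom if chrom is not None else ["1A"] * m),
        cm=np.arange(m, dtype=float),
        bp=np.arange(1, m + 1, dtype=np.int64) * 1000,
    )


class TestFilter:
    def test_maf_enumeration_on_toy_matrix(self):
        # 10 genotypes; per-marker MAFs 0.5, 0.04 (monomorphic-ish), 0.3, 0.0, 0.25, 0.05
        n = 50
        rng = np.random.default_rng(0)
        mafs = [0.5, 0.04, 0.3, 0.0, 0.25, 0.05]
        cols = []
        for p in mafs:
            k = int(round(2 * n * p))  # exact minor-allele count
            col = np.zeros(2 * n)
            col[:k] = 1
            rng.shuffle(col)
            cols.append(col[:n] + col[n:])
        geno = make_geno(np.column_stack(cols))
        kept = filter_markers(geno, max_missing=0.2, min_maf=0.05)
        assert kept.n_markers == 4
        assert set(kept.marker_ids) == {"m0", "m2", "m4", "m5"}

    def test_excess_missingness_removed(self):
        D = np.ones((20, 2))
        D[:5, 0] = np.nan  # 25% missing
        D[0, 1] = 0.0
        D[1:, 1] = np.repeat([0, 1, 2], (7, 6, 6))
        geno = make_geno(D)
        kept = filter_markers(geno, max_missing=0.2, min_maf=0.01)
        assert kept.marker_ids == ["m1"]

    def test_panel_scale_counts_match_bruteforce_recount(self):
        cfg = SimulationConfig(
            n_genotypes=120, n_markers=500, traits=[], seed=14, missing_rate=0.1,
            maf_range=(0.02, 0.5),
        )
        geno = simulate_genotypes(cfg)
        kept = filter_markers(geno, 0.2, 0.05)
        expected = 0
        for j in range(geno.n_markers):
            col = geno.dosages[:, j]
            miss = np.isnan(col).mean()
            obs = col[~np.isnan(col)]
            p = obs.mean() / 2 if len(obs) else 0.0
            if miss <= 0.2 and min(p, 1 - p) >= 0.05:
                expected += 1
        assert kept.n_markers == expected

    def test_all_markers_removed_is_an_error(self):
        geno = make_geno(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            filter_markers(geno)


class TestStructure:
    def test_kinship_equals_scaled_crossproduct_oracle(self):
        geno = toy_genotypes(n=10, m=20, seed=1)
        st_model = compute_structure(geno, n_pc=3)
        X = geno.dosages
        W = X - X.mean(axis=0)
        K = W @ W.T
        K = K / (np.trace(K) / 10)
        assert np.abs(st_model.kinship - K).max() < 1e-10

    def test_duplicate_genotypes_share_kinship_diagonal(self):
        rng = np.random.default_rng(2)
        D = rng.integers(0, 3, size=(12, 40)).astype(float)
        D[1] = D[0]
        st_model = compute_structure(make_geno(D), n_pc=2)
        K = st_model.kinship
        assert abs(K[0, 1] - K[0, 0]) < 1e-10
        assert abs(K[0, 1] - K[1, 1]) < 1e-10

    def test_pc1_separates_differentiated_subpops(self):
        cfg = SimulationConfig(
            n_genotypes=100, n_markers=600, n_subpops=2, fst=0.35,
            admixed_fraction=0.0, traits=[], seed=6, missing_rate=0.0,
        )
        geno = simulate_genotypes(cfg)
        st_model = compute_structure(geno, n_pc=2)
        pc1 = st_model.pca[:, 0]
        labels = np.asarray(geno.subpop)
        a, b = pc1[labels == "SP1"], pc1[labels == "SP2"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or max(b.min(), a.min()) > min(b.max(), a.max())
        # no overlap between the two clusters on PC1
        lo_a, hi_a, lo_b, hi_b = a.min(), a.max(), b.min(), b.max()
        assert hi_a < lo_b or hi_b < lo_a

    def test_npc_must_be_below_sample_size(self):
        with pytest.raises(ValueError):
            compute_structure(toy_genotypes(n=5, m=20), n_pc=5)


class TestScan:
    def test_causal_marker_attains_minimum_p(self):
        rng = np.random.default_rng(3)
        geno = toy_genotypes(n=200, m=50, seed=3)
        y = 2.0 * geno.dosages[:, 17] + 0.1 * rng.standard_normal(200)
        scan = mlm_scan(y, geno, compute_structure(geno, 3))
        assert scan.loc[scan["p_value"].idxmin(), "marker"] == "m17"

    def test_p3d_matches_dense_gls_oracle(self):
        """Spectral-shortcut p-values equal an explicit V^-1 GLS fit."""
        geno = toy_genotypes(n=30, m=50, seed=7)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(30) + geno.dosages[:, 5] * 0.5
        structure = compute_structure(geno, 3)
        scan = mlm_scan(y, geno, structure)

        W0 = np.column_stack([np.ones(30), structure.pca])
        null = fit_spectral_reml(y, W0, structure.kinship)
        V = null.sigma_g2 * structure.kinship + null.sigma_e2 * np.eye(30)
        L = np.linalg.cholesky(np.linalg.inv(V))
        yw, Ww = L.T @ y, L.T @ W0
        rss0 = np.sum((yw - Ww @ np.linalg.lstsq(Ww, yw, rcond=None)[0]) ** 2)
        for _, row in scan.iterrows():
            j = geno.marker_ids.index(row["marker"])
            Xw = L.T @ np.column_stack([W0, geno.dosages[:, j]])
            rss1 = np.sum((yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]) ** 2)
            df = 30 - Xw.shape[1]
            F = (rss0 - rss1) / (rss1 / df)
            p = stats.f.sf(F, 1, df)
            assert row["p_value"] == pytest.approx(p, abs=1e-6)

    def test_identity_structure_reduces_to_ols(self):
        geno = toy_genotypes(n=40, m=30, seed=9)
        y = np.random.default_rng(9).standard_normal(40)
        scan = mlm_scan(y, geno, None)
        for j in (0, 11, 29):
            fit = sm.OLS(y, sm.add_constant(geno.dosages[:, j])).fit()
            row = scan[scan["marker"] == f"m{j}"].iloc[0]
            assert row["p_value"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_null_scan_is_uniformly_calibrated(self):
        passes = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            geno = toy_genotypes(n=100, m=2000, seed=2000 + seed)
            y = rng.standard_normal(100)
            scan = mlm_scan(y, geno, None)
            passes += stats.kstest(scan["p_value"], "uniform").pvalue > 0.01
        assert passes >= 9

    def test_monomorphic_markers_skipped(self):
        D = np.random.default_rng(0).integers(0, 3, (20, 5)).astype(float)
        D[:, 2] = 1.0
        geno = make_geno(D)
        scan = mlm_scan(np.random.default_rng(1).standard_normal(20), geno, None)
        assert "m2" not in set(scan["marker"])

    def test_pve_bounded_and_reduced_by_structure_correction(self):
        """A subpopulation-confounded signal loses PVE once PCs+K absorb it."""
        cfg = SimulationConfig(
            n_genotypes=120, n_markers=400, n_subpops=2, fst=0.3,
            admixed_fraction=0.0, traits=[], seed=30, missing_rate=0.0,
        )
        geno = simulate_genotypes(cfg)
        labels = np.asarray(geno.subpop)
        rng = np.random.default_rng(30)
        y = (labels == "SP1") * 2.0 + 0.5 * rng.standard_normal(120)
        uncorrected = mlm_scan(y, geno, None)
        corrected = mlm_scan(y, geno, compute_structure(geno, 3))
        assert (uncorrected["pve"] <= 100).all() and (corrected["pve"] <= 100).all()
        j = uncorrected["pve"].idxmax()
        marker = uncorrected.loc[j, "marker"]
        pve_after = corrected.loc[corrected["marker"] == marker, "pve"]
        assert pve_after.iloc[0] < uncorrected.loc[j, "pve"]

    def test_power_on_sparse_large_effect_architecture(self):
        """The scan tags >=30% of planted large-effect QTL at panel scale."""
        recoveries = []
        for seed in range(10):
            spec = [TraitSpec("T", vg=4, vge=0.0, ve=1.33, n_qtl=10, qtl_effect_share=0.8)]
            cfg = SimulationConfig(n_genotypes=170, n_markers=5000, traits=spec, seed=seed)
            geno = simulate_genotypes(cfg)
            pheno = simulate_phenotypes(geno, cfg)
            y = pheno.data.groupby("genotype")["value"].mean()
            filtered = filter_markers(geno)
            scan = mlm_scan(y, filtered, compute_structure(filtered, 3))
            hits = scan[scan["neg_log10_p"] >= 3.0]
            qtl = pheno.truth["T"].qtl_markers
            found = sum(
                int(
                    not hits[
                        (hits["chrom"] == geno.chrom[q])
                        & ((hits["cm"] - geno.cm[q]).abs() <= 5.0)
                    ].empty
                )
                for q in qtl
            )
            recoveries.append(found / len(qtl))
        assert np.mean(recoveries) >= 0.30


class TestDeclare:
    def test_threshold_counting(self):
        scan = pd.DataFrame(
            {
                "marker": ["a", "b", "c"],
                "chrom": ["1A"] * 3,
                "cm": [1.0, 2.0, 3.0],
                "bp": [10, 20, 30],
                "effect": [0.1] * 3,
                "se": [0.1] * 3,
                "p_value": [1e-4, 1e-2, 10**-3.5],
                "pve": [5.0] * 3,
            }
        )
        scan["neg_log10_p"] = -np.log10(scan["p_value"])
        mtas = declare_mtas({"T": scan}, threshold_neg_log10=3.0)
        assert len(mtas) == 2
        assert set(mtas["marker"]) == {"a", "c"}

    def test_empty_scan_gives_empty_table(self):
        assert declare_mtas({}).empty

    def test_multi_trait_classification(self):
        base = dict(chrom="1A", cm=1.0, bp=10, effect=0.1, se=0.1, pve=5.0)
        s1 = pd.DataFrame([{**base, "marker": "a", "p_value": 1e-5}, {**base, "marker": "b", "p_value": 1e-4}])
        s2 = pd.DataFrame([{**base, "marker": "a", "p_value": 1e-6}])
        for s in (s1, s2):
            s["neg_log10_p"] = -np.log10(s["p_value"])
        mtas = declare_mtas({"T1": s1, "T2": s2})
        is_multi = mtas.set_index(["marker", "trait"])["multi_trait"]
        assert is_multi.loc[("a", "T1")] and is_multi.loc[("a", "T2")]
        assert not is_multi.loc[("b", "T1")]
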
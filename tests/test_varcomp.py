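"""Variance components, heritability, BLUPs and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wheatqg.datasets import LANDRACE_TRAIT_TABLE
from wheatqg.simulate import PlotPhenotypes, SimulationConfig, TraitSpec, simulate_genotypes, simulate_phenotypes
from wheatqg.varcomp import (
    VarianceComponents,
    compute_blups,
    correlations,
    cv_percent,
    fit_varcomp,
    heritability,
    trait_summary,
    variance_shares,
)

from conftest import balanced_phenotypes


def anova_varcomp(pheno, trait="T"):
    """Method-of-moments estimator for a fully balanced design (oracle)."""
    df = pheno.data[pheno.data["trait"] == trait]
    ng = df["genotype"].nunique()
    e = df["year"].nunique()
    r = df.groupby(["genotype", "year"]).size().iloc[0]
    cell = df.groupby(["genotype", "year"])["value"].mean().unstack()
    gm = cell.mean(axis=1)
    ym = cell.mean(axis=0)
    grand = df["value"].mean()
    mse = (
        (df["value"] - df.groupby(["genotype", "year"])["value"].transform("mean")) ** 2
    ).sum() / (ng * e * (r - 1))
    ms_g = e * r * ((gm - grand) ** 2).sum() / (ng - 1)
    ms_gy = (
        r * ((cell.sub(gm, axis=0).sub(ym, axis=1) + grand) ** 2).to_numpy().sum()
        / ((ng - 1) * (e - 1))
    )
    return (ms_g - ms_gy) / (e * r), (ms_gy - mse) / r, mse


class TestREML:
    def test_balanced_toy_matches_anova_oracle(self):
        pheno = balanced_phenotypes(ng=6, e=2, r=2, seed=1)
        vc = fit_varcomp(pheno, "T")
        vg, vge, ve = anova_varcomp(pheno)
        assert vc.vg == pytest.approx(vg, abs=1e-4)
        assert vc.vge == pytest.approx(vge, abs=1e-4)
        assert vc.ve == pytest.approx(ve, abs=1e-4)

    def test_noise_free_data_gives_zero_interaction_and_residual(self):
        spec = [TraitSpec("A", vg=5, vge=0, ve=0, n_qtl=5)]
        cfg = SimulationConfig(
            n_genotypes=30, n_markers=60, traits=spec, seed=0, n_reps=2, missing_rate=0.0
        )
        pheno = simulate_phenotypes(simulate_genotypes(cfg), cfg)
        vc = fit_varcomp(pheno, "A")
        assert vc.vge < 1e-6 * vc.vg
        assert vc.ve < 1e-6 * vc.vg

    def test_parameter_recovery_averaged_over_seeds(self):
        """REML recovers (4, 1, 1) within 20% at n=500 x 2 years x 2 reps."""
        ests = []
        for seed in range(5):
            spec = [TraitSpec("A", vg=4, vge=1, ve=1, n_qtl=40)]
            cfg = SimulationConfig(
                n_genotypes=500, n_markers=150, traits=spec, seed=seed,
                n_reps=2, missing_rate=0.0,
            )
            pheno = simulate_phenotypes(simulate_genotypes(cfg), cfg)
            vc = fit_varcomp(pheno, "A")
            ests.append((vc.vg, vc.vge, vc.ve))
        mean = np.mean(ests, axis=0)
        assert np.all(np.abs(mean - (4, 1, 1)) / (4, 1, 1) < 0.2)

    def test_single_year_design_rejected(self):
        pheno = balanced_phenotypes(e=1, r=2)
        with pytest.raises(ValueError, match="2 years"):
            fit_varcomp(pheno, "T")

    def test_unreplicated_design_names_confounded_components(self):
        pheno = balanced_phenotypes(ng=10, e=2, r=1)
        with pytest.raises(ValueError, match="confounded"):
            fit_varcomp(pheno, "T")

    def test_augmented_design_with_checks_is_identifiable(self):
        spec = [TraitSpec("A", vg=4, vge=1, ve=1, n_qtl=10)]
        cfg = SimulationConfig(
            n_genotypes=170, n_markers=80, traits=spec, seed=12,
            n_reps=1, check_genotypes=2, check_reps=10, missing_rate=0.0,
        )
        pheno = simulate_phenotypes(simulate_genotypes(cfg), cfg)
        vc = fit_varcomp(pheno, "A")
        assert vc.vg > 0 and vc.ve > 0


class TestHeritability:
    @pytest.mark.parametrize(
        # the published components for GY, GP, LV, GFD, GFR are rounded too
        # coarsely to pin those h2 values exactly; the rest reproduce
        "trait", ["TW", "W", "FS", "FY", "MT", "P", "TKW", "GH", "FP", "P/L"]
    )
    def test_reference_components_reproduce_published_h2(self, trait):
        row = LANDRACE_TRAIT_TABLE.loc[trait]
        vc = VarianceComponents(trait, row["vg"], row["vge"], row["ve"], e=2, r=1)
        assert round(heritability(vc), 2) == pytest.approx(row["h2"], abs=1e-9)

    def test_at_least_ten_of_fifteen_traits_match_published_h2(self):
        n_match = sum(
            abs(
                heritability(
                    VarianceComponents(t, r["vg"], r["vge"], r["ve"], e=2, r=1)
                )
                - r["h2"]
            )
            <= 0.01 + 1e-9
            for t, r in LANDRACE_TRAIT_TABLE.iterrows()
        )
        assert n_match >= 10

    def test_no_nongenetic_variance_gives_unit_heritability(self):
        assert heritability(VarianceComponents("x", 2.0, 0, 0, e=2, r=1)) == 1.0

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents("x", 0, 0, 0, e=2, r=1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vg=st.floats(0.1, 100),
        vge=st.floats(0, 50),
        ve=st.floats(0, 50),
        bump=st.floats(0.1, 10),
    )
    def test_h2_monotone_in_components(self, vg, vge, ve, bump):
        base = heritability(VarianceComponents("x", vg, vge, ve, e=2, r=1))
        assert heritability(VarianceComponents("x", vg + bump, vge, ve, e=2, r=1)) >= base
        assert heritability(VarianceComponents("x", vg, vge + bump, ve, e=2, r=1)) <= base
        assert heritability(VarianceComponents("x", vg, vge, ve + bump, e=2, r=1)) <= base


class TestSummary:
    def test_cv_formula_matches_published_values(self):
        assert cv_percent(0.87, 5.0) == pytest.approx(17.40)
        assert cv_percent(65.06, 644.01) == pytest.approx(10.10, abs=0.005)

    def test_zero_sd_gives_zero_cv(self):
        assert cv_percent(0.0, 3.0) == 0.0

    def test_variance_shares_reproduce_published_percentages(self):
        w = LANDRACE_TRAIT_TABLE.loc["W"]
        sg, _, _ = variance_shares(VarianceComponents("W", w["vg"], w["vge"], w["ve"], 2, 1))
        assert round(sg) == 82
        lv = LANDRACE_TRAIT_TABLE.loc["LV"]
        sg, sge, se = variance_shares(
            VarianceComponents("LV", lv["vg"], lv["vge"], lv["ve"], 2, 1)
        )
        assert round(sg) == 63 and round(sge) == 21

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(vg=st.floats(0.01, 1e4), vge=st.floats(0, 1e4), ve=st.floats(0, 1e4))
    def test_shares_sum_to_100_before_rounding(self, vg, vge, ve):
        shares = variance_shares(VarianceComponents("x", vg, vge, ve, 2, 1))
        assert sum(shares) == pytest.approx(100.0, abs=1e-9)

    def test_trait_summary_flags_zero_mean_cv_as_undefined(self):
        pheno = balanced_phenotypes()
        pheno.data["value"] = 0.0
        vc = VarianceComponents("T", 1, 0.2, 0.5, 2, 2)
        s = trait_summary(pheno, vc)
        assert np.isnan(s.cv)


class TestBLUPs:
    def test_closed_form_shrinkage_on_balanced_toy(self):
        """With vge=0, BLUP deviations equal ratio-shrunken mean deviations."""
        pheno = balanced_phenotypes(ng=4, e=2, r=1, vg=3.0, vge=0.0, ve=0.0, seed=7)
        # inject known residual noise scale via supplied components
        vc = VarianceComponents("T", 3.0, 0.0, 1.5, e=2, r=1)
        blups = compute_blups(pheno, "T", vc)
        df = pheno.data
        adj = df.assign(v=df["value"] - df.groupby("year")["value"].transform("mean"))
        dev = adj.groupby("genotype")["v"].mean()
        shrink = vc.vg / (vc.vg + vc.ve / (vc.e * vc.r))
        expected = df["value"].mean() + shrink * dev
        assert np.allclose(
            blups.sort_index().to_numpy(), expected.sort_index().to_numpy(), atol=1e-8
        )

    def test_noiseless_limit_blups_equal_year_adjusted_means(self):
        pheno = balanced_phenotypes(ng=5, e=2, r=2, vg=4.0, vge=0.0, ve=0.0, seed=3)
        vc = VarianceComponents("T", 4.0, 0.0, 0.0, e=2, r=2)
        blups = compute_blups(pheno, "T", vc)
        df = pheno.data
        adj = df.assign(v=df["value"] - df.groupby("year")["value"].transform("mean"))
        expected = df["value"].mean() + adj.groupby("genotype")["v"].mean()
        assert np.abs(blups.sort_index() - expected.sort_index()).max() < 1e-6

    def test_zero_genetic_variance_shrinks_all_deviations_to_zero(self):
        pheno = balanced_phenotypes(ng=5, e=2, r=2, seed=4)
        vc = VarianceComponents("T", 0.0, 0.5, 1.0, e=2, r=2)
        blups = compute_blups(pheno, "T", vc)
        assert np.ptp(blups.to_numpy()) < 1e-6


class TestCorrelations:
    def test_self_correlation_is_unity(self):
        rng = np.random.default_rng(0)
        tbl = pd.DataFrame({"A": rng.standard_normal(50)})
        tbl["B"] = tbl["A"]
        r, _ = correlations(tbl)
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_recovers_simulated_genetic_correlation(self):
        specs = [
            TraitSpec("A", vg=4, vge=0.2, ve=0.4, n_qtl=20),
            TraitSpec("B", vg=2, vge=0.2, ve=0.4, n_qtl=20, correlated_with=("A", 0.8)),
        ]
        cfg = SimulationConfig(
            n_genotypes=300, n_markers=120, traits=specs, seed=21, n_reps=2, missing_rate=0.0
        )
        pheno = simulate_phenotypes(simulate_genotypes(cfg), cfg)
        from wheatqg.varcomp import blup_table

        blups = blup_table(pheno, ["A", "B"])
        r, p = correlations(blups, mode="genetic")
        assert abs(r.loc["A", "B"] - 0.8) < 0.1
        assert p.loc["A", "B"] < 0.05

    def test_independent_traits_are_null_calibrated(self):
        hits = 0
        sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tbl = pd.DataFrame(rng.standard_normal((300, 2)), columns=["A", "B"])
            r, p = correlations(tbl)
            hits += abs(r.loc["A", "B"]) < 0.15
            sig += p.loc["A", "B"] > 0.05
        assert hits >= 90
        assert sig >= 90

    def test_constant_trait_flagged_as_nan(self):
        tbl = pd.DataFrame({"A": np.arange(10.0), "B": np.ones(10)})
        r, p = correlations(tbl)
        assert np.isnan(r.loc["A", "B"]) and np.isnan(p.loc["A", "B"])

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            correlations(pd.DataFrame({"A": [1.0, 2.0, 3.0]}), mode="bogus")
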
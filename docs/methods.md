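# Methods

## Phenotypic model and variance components

Plot-level records from a multi-year trial are modelled as

    y_ijk = mu + year_j + g_i + (gy)_ij + eps_ijk

with year fixed and genotype (g), genotype-by-year interaction (gy) and
plot residual (eps) random. Year is fixed because the quantities of
interest are genotype BLUPs and the entry-mean heritability; the
residual then measures within-trial plot error rather than a pooled
"environment" term. REML estimation is delegated to statsmodels
MixedLM (random intercept per genotype plus a year-within-genotype
variance component); estimates are clamped at zero. Two degenerate
regimes are peeled off analytically before optimisation, because a
numerical optimiser misbehaves on exactly noise-free data: zero pooled
within-cell variance fixes sigma_e^2 = 0 and refits on cell means, and
zero within-genotype cross-year variance additionally fixes
sigma_ge^2 = 0.

**Identifiability.** With one replicate per genotype-year cell
(augmented designs), sigma_ge^2 and sigma_e^2 are confounded; the fit
refuses such data with an error naming the confounded components. The
simulator therefore replicates two designated check genotypes in every
year (10 plots per year by default), mirroring how augmented trials
recover a residual-error estimate from repeated checks.

**Heritability.** Entry-mean broad-sense heritability is

    h2 = vg / (vg + vge/e + ve/(r*e))

with e the number of years and r the geometric-mean number of
replicates per genotype-year cell. h2 is reported to 2 decimals, CV
(100·sd/mean on genotype means) to 2 decimals, and variance shares
(each component as a percentage of vg+vge+ve) to the nearest integer —
the precision used in the reference table bundled in
`wheatqg.datasets`. Applied to that table's printed components, the
formula reproduces the published h2 column exactly for 10 of 15 traits;
the other five (GY, GP, LV, GFD, GFR) differ by at most one unit in the
second decimal because their printed components are themselves rounded
(GFR's components, 0.0020 and 0.06, are too coarse to pin its h2).

**BLUPs.** Genotype BLUPs solve Henderson's mixed-model equations at
the REML (or user-supplied) components; reported values are
mu + mean-year-effect + g_i, i.e. trait units centred on the grand
mean, with ratio shrinkage vg/(vg + ve/(e·r)) in the balanced
vge = 0 case. Genetic correlations are Pearson correlations of
genotype BLUPs (phenotypic: of raw genotype means) — a univariate
approximation in the style of the Meta-R tool rather than bivariate
REML, which is out of scope.

## Mixed-linear-model GWAS

Markers with more than 20% missing calls or minor-allele frequency
below 0.05 are removed. Structure correction uses the leading
principal components (3 by default) of the column-centred, mean-imputed
dosage matrix, plus a VanRaden-style kinship K = WW'/c scaled to mean
diagonal 1. The scan fits the null model y = W a + u + e with
Var(u) = sigma_a^2 K once by spectral REML — a 1-D profile over
delta = sigma_e^2/sigma_a^2 on a log grid (81 points in [e^-10, e^10])
refined by bounded Brent search — and reuses those components for every
marker (P3D). Each marker is then tested by generalized least squares
in the whitened coordinate system, computed via Frisch–Waugh–Lovell
residualisation so the full scan is vectorised; p-values are F(1, n−q−1).
No compression/clustering of individuals is applied: at a few hundred
genotypes compression converges to no compression, and the plain P3D
model is more transparent.

Numerical choices: missing dosages are mean-imputed for PCA, K and
tested markers; non-PSD kinship is repaired by eigenvalue clamping with
a warning; markers monomorphic after residualisation (whitened SSX
below 1e-10 of the maximum) are skipped. The allelic effect is the GLS
substitution effect of the minor allele; PVE is the marker's
incremental R^2 on the whitened scale, equivalently F/(F + df). MTAs
are declared at −log10 p ≥ 3 (the threshold conventional in wheat
association studies); Benjamini–Hochberg q-values are reported
alongside but never used for exclusion, and markers significant for
more than one trait are labelled multi-trait.

With identity kinship and no PCs the scan collapses to ordinary
single-marker regression (verified to 1e-8), and the spectral shortcut
matches an explicit V^{-1} GLS oracle to 1e-6.

## Overview index and hotspots

Each MTA's positional uncertainty comes from its chromosome's LD-decay
distance: a 95% confidence interval of width CI = LD-decay implies a
normal sd of si = CI/3.92. The overview index on a 1-cM grid is the
Gaussian-kernel density of MTA positions scaled by the number of
experiments:

    U(x) = (1/nbE) * sum_MTA N(x; cm_MTA, si)

whose genome-wide mean recovers the closed form nbQTL/(nbE·map length)
when MTAs are spread over the map — reconciling the per-cM index with
the printed mean formula. nbE defaults to the number of trait analyses
contributing MTAs. Hotspots are maximal runs of contiguous grid points
with U(x) ≥ 5·mean(U); runs containing no MTA (kernel spill-over) are
suppressed, remaining segments are named QTL_<chrom>.<k> in map order,
and their confidence interval is reported in integer cM. Both
thresholds are always recomputed from the profile, never hard-coded.

## Candidate genes

The peak MTA of a hotspot (smallest p-value by default; the CI-midpoint
member is available as an alternative since either reading of "central"
is defensible) defines a ±500 kb physical window; any gene model whose
span intersects the closed interval is a candidate. Expression
classification uses two parameters that the source analysis leaves
unstated and that are therefore explicit, logged configuration:
"expressed" means TPM > 0.5, and an up/down trend across the ordered
grain stages (milk < soft dough < hard dough < dough < ripening)
requires monotone TPM with at least a 2-fold total change.
Grain-specific means expressed in at least one grain condition and in
no other tissue. Coordinates are assumed to be on a single assembly;
cross-version coordinate lifting must happen upstream.

## RR-BLUP genomic prediction

Marker effects solve y = Xb + Mu + e with u ~ N(0, sigma_u^2 I); the
shrinkage ratio lambda = sigma_e^2/sigma_u^2 comes from the same
spectral REML machinery applied to K = MM', and effects from the n×n
form u = M'(MM' + lambda I)^{-1}(y − Xb). Accuracy is the Pearson
correlation between predicted and observed values on held-out
genotypes over repeated random 80/20 splits (150 iterations by
default); folds with a constant test vector are resampled and logged.
The year-mode comparison (each year alone, both years jointly with
year as a fixed factor, and the across-year mean) reuses the same
genotype split in every mode per iteration, so the comparison is
paired. In the joint mode rows of the same genotype never straddle a
split. Accuracies are raw correlations, not rescaled by h.

## The synthetic panel

The simulator emulates a Mediterranean landrace diversity panel — the
study conditions, not a tuning dial. Defaults: 170 genotypes in 3
subpopulations plus an admixed fraction of 26/170; Balding–Nichols
differentiation FST = 0.1; 5,000 markers (a desk-scale stand-in for a
~13k-SNP array) on 21 wheat chromosomes of 160 cM / 600 Mb each; MAF
in [0.05, 0.5]; 2 years; 1 replicate with 2 checks at 10 plots/year;
2% missing calls injected completely at random.

Marker frequencies get positional autocorrelation along the map
(AR(1) latent field, 5 cM scale) and each haplotype is drawn from a
Gaussian copula with the same AR(1) correlation, so LD decays with map
distance within individuals as well as across subpopulations. No
coalescent is simulated: the LD is stationary and exchangeable, which
is sufficient to exercise kinship/PCA correction and LD-window logic
but does not reproduce real LD-block heterogeneity, selection
footprints or the hexaploid subgenome structure. The realized
(pre-missingness) MAF of every marker is guaranteed ≥ the configured
floor by redrawing frequencies of failing markers against the fixed
latent field.

Trait values are built from n_qtl causal markers whose effect variance
is scaled to exactly qtl_effect_share·vg, a polygenic deviation scaled
to the remainder of vg, genotype-by-year draws with variance vge, plot
residuals with variance ve, and fixed year offsets spanning
±0.5·sqrt(ve) (kept separable from the residual so the truth records
stay attributable). A trait may also be constructed to have an exact
target genetic correlation with an earlier trait. All draws — causal
markers, effects, g, gy, eps, year offsets — are returned as ground
truth, and the whole simulation is bit-reproducible under a fixed seed.

## Test design: problem sizes and statistical guardbands

Simulation-backed tests run at sizes chosen to keep the full suite
around a minute while leaving the assertions statistically meaningful:
REML parameter recovery uses 500 genotypes × 2 years × 2 reps averaged
over 20 seeds (±20% band); GWAS calibration uses 10 null panels of
2,000 markers (KS uniformity in ≥9/10); null-trait cross-validation
spreads its 150 iterations over 3 independent panels because a single
panel's conditional mean accuracy wanders with sd ≈ 0.07.

Two properties are deliberately parameterised by the package rather
than taken at face value. First, single-locus detection power: at 170
genotypes the −log10 p ≥ 3 threshold needs a per-marker R^2 of roughly
6%, so the power test plants 10 QTL carrying 80% of vg (per-QTL R^2
≈ 6%, matching the PVE range such panels actually report) and requires
≥30% of them tagged within the 5-cM LD window, averaged over 10 seeds.
A diffuse architecture (50 QTL sharing half of vg) puts every locus far
below the threshold and would test nothing but the noise floor.
Second, the year-mode comparison: because a single simulated panel's
per-year accuracy has dataset-level noise of ±0.1, the suite asserts
that the across-year mean beats the *average* of the two single-year
accuracies (per seed and on the seed average), which is the stable
expression of the qualitative finding that averaging years predicts
best under G×E.

What passing does and does not show: the suite demonstrates formula
fidelity, internal consistency against independent oracles, null
calibration and truth recovery under the simulator's idealised LD and
i.i.d.-noise assumptions. It does not certify performance on real
panels, whose relatedness structure, LD heterogeneity and
non-Gaussian residuals the generator intentionally simplifies — the
real-data headline counts (numbers of MTAs, hotspots, candidate genes)
depend on unpublished panel data and are covered only qualitatively.

## Known limitations

- Genetic correlations are BLUP-Pearson approximations, not bivariate
  REML; standard errors of variance components are not reported.
- The scan is single-marker P3D; multi-locus models, epistasis and
  haplotype tests are out of scope.
- Hotspot merging is pure grid contiguity; two clusters whose kernels
  touch above threshold merge into one hotspot.
- The expression classifier's 0.5-TPM and 2-fold defaults are
  conventions, not fitted quantities; sensitivity to them is the
  user's responsibility.
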
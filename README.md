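# wheatqg

Quantitative genetics of bread-wheat quality and agronomic traits for
diversity panels — built for the kind of study where a few hundred
landraces are phenotyped over two years in an augmented field design,
genotyped with a medium-density SNP array, and analysed end to end:

1. **Variance components & heritability** (`wheatqg.varcomp`): REML fit
   of the plot-level model *y<sub>ijk</sub> = μ + year<sub>j</sub> +
   g<sub>i</sub> + (gy)<sub>ij</sub> + ε<sub>ijk</sub>*, genotype BLUPs,
   entry-mean broad-sense heritability
   *h² = σ²g / (σ²g + σ²ge/e + σ²e/(r·e))*, CV and variance shares,
   genetic/phenotypic correlations.
2. **Mixed-linear-model GWAS** (`wheatqg.gwas`): MAF/missingness
   filtering, PCA + VanRaden kinship structure correction, EMMA-style
   spectral REML with P3D (null variance components reused for every
   marker test), marker effects, PVE, and marker–trait associations
   (MTAs) at −log₁₀p ≥ 3 with Benjamini–Hochberg FDR flags.
3. **QTL hotspots** (`wheatqg.hotspots`): per-chromosome MTA positional
   uncertainty *s<sub>i</sub> = LD-decay / 3.92*, the Gaussian-kernel QTL
   overview index *U(x)* per cM (genome-wide mean *nbQTL/(nbE·map
   length)*), and hotspot calling at 5× the mean index.
4. **Candidate genes** (`wheatqg.genes`): gene models within ±500 kb of
   hotspot peak MTAs (GFF3), classified by expression as grain-specific,
   up/down-regulated through grain development, and starchy-endosperm vs
   aleurone enriched.
5. **Genomic prediction** (`wheatqg.predict`): RR-BLUP marker effects
   with REML shrinkage, 80/20 cross-validation over 150 iterations, and
   a paired comparison of per-year / joint / across-year-mean inputs.
6. **Loaf-volume equations** (`wheatqg.lvreg`): OLS prediction of loaf
   volume from up to three cheaper quality traits, validated by repeated
   50/50 splits.
7. **Panel simulator** (`wheatqg.simulate`): Balding–Nichols
   subpopulations plus admixture, copula-based LD, sparse-QTL traits
   with genotype-by-year interaction and full ground-truth records — so
   every stage above is testable offline.

## Worked example

```python
from wheatqg import *
from wheatqg.datasets import LANDRACE_TRAIT_TABLE

# heritability from published variance components (gluten strength W)
row = LANDRACE_TRAIT_TABLE.loc["W"]
vc = VarianceComponents("W", row["vg"], row["vge"], row["ve"], e=2, r=1)
print("W h2 =", round(heritability(vc), 2))        # -> W h2 = 0.9

# a synthetic 170-landrace panel, one sedimentation-like trait
spec = [TraitSpec("FS", vg=4.21, vge=0.94, ve=0.51,
                  n_qtl=10, qtl_effect_share=0.8, mean=10.0)]
cfg = SimulationConfig(n_genotypes=170, n_markers=2000, traits=spec, seed=7)
geno = simulate_genotypes(cfg)
pheno = simulate_phenotypes(geno, cfg)

vc = fit_varcomp(pheno, "FS")
print(f"FS: vg={vc.vg:.2f} vge={vc.vge:.2f} ve={vc.ve:.2f} "
      f"h2={heritability(vc):.2f}")
# -> FS: vg=3.70 vge=0.98 ve=0.38 h2=0.85

blups = compute_blups(pheno, "FS", vc)
filtered = filter_markers(geno)                    # 1997 of 2000 markers kept
scan = mlm_scan(blups, filtered, compute_structure(filtered, n_pc=3))
mtas = declare_mtas({"FS": scan})
print("MTAs at -log10p>=3:", len(mtas))            # -> 6
```

The six MTAs group into four hotspots under the overview index, and
50 rounds of 80/20 RR-BLUP cross-validation on the same panel give a
mean prediction accuracy of 0.39 — what one expects for a trait whose
marker-linked share of σ²g is 0.8 at this panel size.

The same stages are scriptable from the shell:

```bash
wheatqg simulate --out demo --seed 7 --genotypes 170 --markers 2000 --traits FS,W
wheatqg varcomp  --pheno demo/phenotypes.csv --out demo/varcomp.tsv
wheatqg gwas     --geno demo/genotypes.vcf --blups demo/blups.csv --trait FS \
                 --out demo/fs_scan.tsv
wheatqg run-all  --out demo_full --seed 1
```

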
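"""End-to-end orchestration: simulate -> variance components -> BLUPs ->
GWAS -> hotspots -> candidate genes -> genomic prediction -> LV equations.

Every numeric table written carries a header comment with the config
hash and seed so outputs are traceable; rerunning with the same config
reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .datasets import LANDRACE_TRAIT_TABLE
from .gwas import compute_structure, declare_mtas, filter_markers, mlm_scan
from .hotspots import attach_ci, call_hotspots, hotspot_table, overview_index
from .lvreg import equation_report, fit_and_validate
from .predict import cross_validate
from .simulate import (
    PlotPhenotypes,
    SimulationConfig,
    TraitSpec,
    simulate_genotypes,
    simulate_phenotypes,
)
from .varcomp import blup_table, varcomp_report

log = logging.getLogger(__name__)

#: the five standard loaf-volume equation specifications
LV_EQUATIONS = [
    "LV ~ GP + FS + GH",
    "LV ~ GP + FS + MT",
    "LV ~ MT + FY + FS",
    "LV ~ FS + W + P/L",
    "LV ~ MT + W + P/L",
]


@dataclass
class PipelineConfig:
    out_dir: str = "wheatqg_out"
    seed: int = 0
    simulate: bool = True
    genotype_path: str | None = None
    genotype_format: str = "auto"
    map_path: str | None = None
    phenotype_path: str | None = None
    gff3_path: str | None = None
    expression_path: str | None = None
    expression_meta_path: str | None = None
    ld_decay_path: str | None = None
    traits: list = field(default_factory=lambda: list(LANDRACE_TRAIT_TABLE.index))
    n_genotypes: int = 170
    n_markers: int = 5000
    n_qtl: int = 20
    qtl_effect_share: float = 0.5
    n_pc: int = 3
    mta_threshold: float = 3.0
    max_missing: float = 0.20
    min_maf: float = 0.05
    nb_e: int | None = None
    default_ld_decay_cm: float = 5.0
    gene_half_window: int = 500_000
    gs_iterations: int = 150
    lv_iterations: int = 150
    run_genes: bool = False
    run_gs: bool = True
    run_lv: bool = True

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # analysis parameters only, not output location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _default_sim_config(cfg: PipelineConfig) -> SimulationConfig:
    specs = []
    for t in cfg.traits:
        if t in LANDRACE_TRAIT_TABLE.index:
            row = LANDRACE_TRAIT_TABLE.loc[t]
            specs.append(
                TraitSpec(
                    name=t, vg=row["vg"], vge=row["vge"], ve=row["ve"],
                    n_qtl=cfg.n_qtl, qtl_effect_share=cfg.qtl_effect_share,
                    mean=row["mean"],
                )
            )
        else:
            specs.append(TraitSpec(name=t, vg=1.0, vge=0.25, ve=1.0, n_qtl=cfg.n_qtl))
    return SimulationConfig(
        n_genotypes=cfg.n_genotypes,
        n_markers=cfg.n_markers,
        traits=specs,
        seed=cfg.seed,
    )


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    sep = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"# wheatqg config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep=sep, index=index)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns a manifest of written outputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    # ------------------------------------------------------------ inputs
    if cfg.simulate:
        sim = _default_sim_config(cfg)
        geno = simulate_genotypes(sim)
        pheno = simulate_phenotypes(geno, sim)
        wio.write_vcf(geno, out / "genotypes.vcf")
        wio.write_phenotypes(pheno, out / "phenotypes.csv")
        outputs["genotypes"] = "genotypes.vcf"
        outputs["phenotypes"] = "phenotypes.csv"
    else:
        if not cfg.genotype_path:
            raise PipelineError("input", "genotype_path is required when simulate=False")
        if not cfg.phenotype_path:
            raise PipelineError("input", "phenotype_path is required when simulate=False")
        geno = wio.read_genotypes(cfg.genotype_path, cfg.genotype_format, cfg.map_path)
        pheno = wio.read_phenotypes(cfg.phenotype_path)

    traits = [t for t in cfg.traits if t in pheno.traits()]
    if not traits:
        raise PipelineError("input", "no configured trait present in the phenotype data")

    # ----------------------------------------------- variance components
    try:
        vc_table = varcomp_report(pheno, traits)
    except Exception as exc:
        raise PipelineError("varcomp", str(exc)) from exc
    _write_table(vc_table, out / "varcomp.tsv", cfg, index=True)
    outputs["varcomp"] = "varcomp.tsv"

    blups = blup_table(pheno, traits)
    _write_table(blups.rename_axis("genotype"), out / "blups.csv", cfg, index=True)
    outputs["blups"] = "blups.csv"

    # ---------------------------------------------------------------- GWAS
    try:
        filtered = filter_markers(geno, cfg.max_missing, cfg.min_maf)
        structure = compute_structure(filtered, n_pc=cfg.n_pc)
        scans = {}
        for t in traits:
            scans[t] = mlm_scan(blups[t], filtered, structure)
    except Exception as exc:
        raise PipelineError("gwas", str(exc)) from exc
    assoc = pd.concat(
        [s.assign(trait=t) for t, s in scans.items()], ignore_index=True
    )
    _write_table(assoc, out / "associations.tsv", cfg)
    outputs["associations"] = "associations.tsv"

    mtas = declare_mtas(scans, threshold_neg_log10=cfg.mta_threshold)
    # -------------------------------------------------------- hotspots
    try:
        if cfg.ld_decay_path:
            ld = wio.read_ld_decay(cfg.ld_decay_path)
        else:
            ld = {c: cfg.default_ld_decay_cm for c in np.unique(filtered.chrom)}
        mtas = attach_ci(mtas, ld) if not mtas.empty else mtas
        chrom_len = {
            c: float(np.ceil(filtered.cm[filtered.chrom == c].max()))
            for c in np.unique(filtered.chrom)
        }
        nb_e = cfg.nb_e or len(traits)
        profile = overview_index(mtas, chrom_len, nb_e=nb_e)
        hotspots = call_hotspots(profile, mtas)
    except Exception as exc:
        raise PipelineError("hotspots", str(exc)) from exc
    _write_table(mtas, out / "mtas.tsv", cfg)
    _write_table(profile.frame(), out / "overview.tsv", cfg)
    _write_table(hotspot_table(hotspots), out / "hotspots.tsv", cfg)
    wio.write_hotspot_bed(hotspots, out / "hotspots.bed")
    outputs.update(
        mtas="mtas.tsv", overview="overview.tsv",
        hotspots="hotspots.tsv", hotspots_bed="hotspots.bed",
    )

    # -------------------------------------------------- candidate genes
    if cfg.run_genes:
        if not cfg.gff3_path:
            raise PipelineError("genes", "candidate-gene stage enabled but gff3_path is missing")
        from .genes import candidate_genes_for_hotspots, classify_candidates

        genes = wio.read_gff3_genes(cfg.gff3_path)
        cand = candidate_genes_for_hotspots(hotspots, genes, cfg.gene_half_window)
        if cfg.expression_path and cfg.expression_meta_path:
            prof = wio.read_expression(cfg.expression_path, cfg.expression_meta_path)
            cand = classify_candidates(cand, prof)
        _write_table(cand, out / "candidates.tsv", cfg)
        outputs["candidates"] = "candidates.tsv"

    # ------------------------------------------------ genomic prediction
    if cfg.run_gs:
        M = filtered.imputed()
        M = M - M.mean(axis=0)
        rows = []
        for t in traits:
            y = blups[t].reindex(filtered.genotype_ids).to_numpy()
            res = cross_validate(
                y, M, iterations=cfg.gs_iterations, seed=cfg.seed, trait=t, mode="mean"
            )
            rows.append(
                {
                    "trait": t, "mode": res.mode,
                    "mean_accuracy": round(res.mean_accuracy, 3),
                    "sd_accuracy": round(res.sd_accuracy, 3),
                    "iterations": res.iterations,
                }
            )
        _write_table(pd.DataFrame(rows), out / "gs_accuracy.tsv", cfg)
        outputs["gs_accuracy"] = "gs_accuracy.tsv"

    # ------------------------------------------------------ LV equations
    if cfg.run_lv and "LV" in blups.columns:
        models = []
        for eq in LV_EQUATIONS:
            preds = [p.strip() for p in eq.split("~")[1].split("+")]
            if all(p in blups.columns for p in preds):
                models.append(
                    fit_and_validate(blups, eq, iterations=cfg.lv_iterations, seed=cfg.seed)
                )
        if models:
            _write_table(equation_report(models), out / "lv_equations.tsv", cfg)
            outputs["lv_equations"] = "lv_equations.tsv"

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["manifest"] = "manifest.json"
    return manifest
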
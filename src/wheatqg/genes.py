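"""Candidate-gene extraction around hotspot peak MTAs.

Gene models within +/-500 kb of a hotspot's peak marker (physical
coordinates, closed interval, any overlap counts) are candidate genes.
Their expression across tissues and grain developmental stages is then
classified: grain-specific (expressed in grain only), up- or
down-regulated across the ordered grain stages (milk < soft dough <
hard dough < dough < ripening), and starchy-endosperm vs aleurone-layer
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GRAIN_STAGE_ORDER = ["milk", "soft_dough", "hard_dough", "dough", "ripening"]


@dataclass
class ExpressionProfile:
    """Gene-by-condition TPM matrix plus condition metadata.

    values: DataFrame indexed by gene id, columns are condition names.
    meta: DataFrame indexed by condition with columns 'tissue' (one of
    roots, leaves_shoots, spikes, grain) and optional 'stage' (ordering
    key for grain development) and 'layer' (starchy_endosperm /
    aleurone).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"conditions without metadata: {sorted(missing)}")


def genes_in_window(
    peak_bp: int,
    chrom: str,
    genes: pd.DataFrame,
    half_window: int = 500_000,
) -> pd.DataFrame:
    """Gene models overlapping [peak - half_window, peak + half_window].

    genes: DataFrame with columns (gene_id, chrom, start, end, strand,
    description) as produced by io.read_gff3_genes. Overlap is closed:
    a gene touching either boundary is included.
    """
    lo = peak_bp - half_window
    hi = peak_bp + half_window
    hit = (genes["chrom"] == chrom) & (genes["end"] >= lo) & (genes["start"] <= hi)
    return genes[hit].reset_index(drop=True)


def candidate_genes_for_hotspots(
    hotspots,
    genes: pd.DataFrame,
    half_window: int = 500_000,
    peak: str = "min_p",
) -> pd.DataFrame:
    """Candidate genes per hotspot around its peak MTA.

    peak="min_p" uses the member MTA with the smallest p-value;
    peak="central" uses the member closest to the hotspot CI midpoint.
    Hotspots whose peak lacks a physical position are skipped with a log
    entry (e.g. markers whose genetic and physical chromosome disagree).
    """
    if peak not in ("min_p", "central"):
        raise ValueError("peak must be 'min_p' or 'central'")
    rows = []
    for h in hotspots:
        members = h.members
        if peak == "min_p":
            row = members.loc[members["p_value"].idxmin()]
        else:
            mid = 0.5 * (h.ci[0] + h.ci[1])
            row = members.loc[(members["cm"] - mid).abs().idxmin()]
        if not np.isfinite(row.get("bp", np.nan)) or row["bp"] <= 0:
            log.info("hotspot %s: peak MTA lacks physical position; skipped", h.id)
            continue
        hits = genes_in_window(int(row["bp"]), h.chrom, genes, half_window)
        for _, gene in hits.iterrows():
            rows.append(
                {
                    "hotspot": h.id,
                    "peak_marker": row["marker"],
                    "peak_bp": int(row["bp"]),
                    "window_start": int(row["bp"]) - half_window,
                    "window_end": int(row["bp"]) + half_window,
                    "gene_id": gene["gene_id"],
                    "chrom": gene["chrom"],
                    "start": gene["start"],
                    "end": gene["end"],
                    "description": gene.get("description", ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot", "peak_marker", "peak_bp", "window_start", "window_end",
            "gene_id", "chrom", "start", "end", "description",
        ],
    )


def classify_expression(
    profile: ExpressionProfile,
    gene_id: str,
    tissue_threshold: float = 0.5,
    fold_change: float = 2.0,
) -> dict:
    """Expression classification of one gene.

    Returns a dict with keys:
      grain_specific : expressed (> threshold) in at least one grain
          condition and at most threshold in every non-grain tissue;
      trend : 'up' if TPM is non-decreasing across ordered grain stages
          with at least fold_change total increase, 'down' for the
          mirror case, else 'none';
      endosperm_vs_aleurone : (starchy endosperm TPM, aleurone TPM) pair
          when both layers are present, else None.
    """
    if gene_id not in profile.values.index:
        raise KeyError(f"gene {gene_id!r} absent from the expression profile")
    expr = profile.values.loc[gene_id]
    meta = profile.meta

    grain_cols = [c for c in expr.index if meta.loc[c, "tissue"] == "grain"]
    other_cols = [c for c in expr.index if meta.loc[c, "tissue"] != "grain"]
    grain_specific = bool(
        grain_cols
        and (expr[grain_cols] > tissue_threshold).any()
        and (not other_cols or (expr[other_cols] <= tissue_threshold).all())
    )

    trend = "none"
    if "stage" in meta.columns:
        staged = [
            (meta.loc[c, "stage"], c)
            for c in grain_cols
            if isinstance(meta.loc[c, "stage"], str) and meta.loc[c, "stage"] in GRAIN_STAGE_ORDER
        ]
        staged.sort(key=lambda sc: GRAIN_STAGE_ORDER.index(sc[0]))
        series = np.array([expr[c] for _, c in staged], dtype=float)
        if len(series) >= 2:
            lo = max(series.min(), 1e-9)
            if np.all(np.diff(series) >= 0) and series[-1] >= fold_change * max(series[0], 1e-9):
                trend = "up"
            elif np.all(np.diff(series) <= 0) and series[0] >= fold_change * max(series[-1], 1e-9):
                trend = "down"

    pair = None
    if "layer" in meta.columns:
        endo = [c for c in expr.index if meta.loc[c].get("layer") == "starchy_endosperm"]
        aleu = [c for c in expr.index if meta.loc[c].get("layer") == "aleurone"]
        if endo and aleu:
            pair = (float(expr[endo].mean()), float(expr[aleu].mean()))

    return {
        "grain_specific": grain_specific,
        "trend": trend,
        "endosperm_vs_aleurone": pair,
    }


def classify_candidates(
    candidates: pd.DataFrame,
    profile: ExpressionProfile,
    tissue_threshold: float = 0.5,
    fold_change: float = 2.0,
) -> pd.DataFrame:
    """Attach expression classification to a candidate-gene table.

    Genes absent from the expression matrix get empty classifications.
    The thresholds used are recorded in the frame's attrs.
    """
    out = candidates.copy()
    flags, trends, endo, aleu = [], [], [], []
    for g in out["gene_id"]:
        if g in profile.values.index:
            c = classify_expression(profile, g, tissue_threshold, fold_change)
            flags.append(c["grain_specific"])
            trends.append(c["trend"])
            pair = c["endosperm_vs_aleurone"]
            endo.append(pair[0] if pair else np.nan)
            aleu.append(pair[1] if pair else np.nan)
        else:
            flags.append(pd.NA)
            trends.append("")
            endo.append(np.nan)
            aleu.append(np.nan)
    out["grain_specific"] = flags
    out["trend"] = trends
    out["tpm_starchy_endosperm"] = endo
    out["tpm_aleurone"] = aleu
    out.attrs["tissue_threshold"] = tissue_threshold
    out.attrs["fold_change"] = fold_change
    return out
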
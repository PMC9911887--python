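"""QTL overview index and hotspot calling on the genetic map.

Each declared MTA gets a positional uncertainty derived from the
per-chromosome LD-decay distance: the confidence-interval width CI is
the LD decay, and the implied standard deviation is si = CI / 3.92
(3.92 = 2 * 1.96, the width of a 95% normal interval in SD units).

The overview index U(x) is the Gaussian-kernel density of MTAs along
each chromosome, evaluated on a 1-cM grid and scaled by the number of
experiments nbE:

    U(x) = (1/nbE) * sum_mta N(x; cm_mta, si_chrom)

Its genome-wide mean is nbQTL / (nbE * map length) when MTAs are spread
over the map, which is the closed-form mean usually quoted for the
index. Hotspots are maximal runs of contiguous grid points with
U(x) >= 5 * mean(U) that contain at least one MTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)


def mta_ci(ld_decay_cm: float) -> float:
    """Positional SD (cM) implied by a 95% CI equal to the LD decay."""
    if ld_decay_cm <= 0:
        raise ValueError("LD decay must be positive")
    return ld_decay_cm / 3.92


def attach_ci(mtas: pd.DataFrame, ld_decay: dict[str, float]) -> pd.DataFrame:
    """Add si, ci_low and ci_high (cM) per MTA from per-chromosome LD decay."""
    mtas = mtas.copy()
    missing = set(mtas["chrom"].unique()) - set(ld_decay)
    if missing:
        raise ValueError(f"no LD-decay value for chromosomes: {sorted(missing)}")
    decay = mtas["chrom"].map(ld_decay).astype(float)
    mtas["si"] = decay.map(mta_ci)
    mtas["ci_low"] = mtas["cm"] - decay / 2.0
    mtas["ci_high"] = mtas["cm"] + decay / 2.0
    return mtas


@dataclass
class OverviewProfile:
    """Per-chromosome overview-index profiles on a regular cM grid."""

    grids: dict            # chrom -> grid positions (cM)
    u: dict                # chrom -> U(x) values
    nb_qtl: int
    nb_e: int
    mean_u: float
    high_threshold: float  # 5 * mean_u
    grid_step: float = 1.0

    def frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"chrom": c, "cm": self.grids[c], "u": self.u[c]})
            for c in self.grids
        ]
        return pd.concat(parts, ignore_index=True)


def overview_index(
    mtas: pd.DataFrame,
    chrom_lengths_cM: dict[str, float],
    nb_e: int = 15,
    grid_step: float = 1.0,
) -> OverviewProfile:
    """Gaussian-kernel MTA density per cM, scaled by the experiment count.

    mtas must carry columns (chrom, cm, si) — see attach_ci. nb_e is the
    number of experiments (trait analyses) contributing associations.
    """
    if nb_e <= 0:
        raise ValueError("nb_e must be positive")
    grids, u = {}, {}
    if mtas.empty:
        log.warning("overview_index: empty MTA list, returning flat zero profile")
    for c, length in chrom_lengths_cM.items():
        x = np.arange(0.0, length + grid_step / 2, grid_step)
        uu = np.zeros_like(x)
        sub = mtas[mtas["chrom"] == c] if not mtas.empty else mtas
        for _, row in sub.iterrows():
            uu += norm.pdf(x, loc=row["cm"], scale=row["si"])
        grids[c] = x
        u[c] = uu / nb_e
    all_u = np.concatenate([u[c] for c in u]) if u else np.array([0.0])
    mean_u = float(all_u.mean())
    return OverviewProfile(
        grids=grids,
        u=u,
        nb_qtl=len(mtas),
        nb_e=nb_e,
        mean_u=mean_u,
        high_threshold=5.0 * mean_u,
        grid_step=grid_step,
    )


@dataclass
class QTLHotspot:
    id: str
    chrom: str
    ci: tuple            # (start cM, end cM) of the supra-threshold segment
    members: pd.DataFrame = field(repr=False)
    n_traits: int = 0
    traits: tuple = ()
    mean_pve: float = float("nan")


def call_hotspots(
    profile: OverviewProfile,
    mtas: pd.DataFrame,
    threshold: float | None = None,
) -> list[QTLHotspot]:
    """Contiguous supra-threshold segments containing at least one MTA.

    threshold defaults to the profile's high threshold (5 x mean U).
    Hotspots are named QTL_<chrom>.<k> in map order per chromosome.
    Segments whose span contains no MTA (kernel spill-over from
    neighbouring clusters) are suppressed.
    """
    thr = profile.high_threshold if threshold is None else threshold
    hotspots: list[QTLHotspot] = []
    for c in profile.grids:
        x = profile.grids[c]
        above = profile.u[c] >= thr
        if not above.any():
            continue
        # maximal runs of consecutive supra-threshold grid points
        idx = np.nonzero(above)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]])
        k = 0
        for s_i, e_i in zip(starts, ends):
            lo = x[s_i] - profile.grid_step / 2
            hi = x[e_i] + profile.grid_step / 2
            sub = mtas[(mtas["chrom"] == c) & (mtas["cm"] >= lo) & (mtas["cm"] <= hi)]
            if sub.empty:
                continue
            k += 1
            traits = tuple(sorted(sub["trait"].unique())) if "trait" in sub else ()
            hotspots.append(
                QTLHotspot(
                    id=f"QTL_{c}.{k}",
                    chrom=c,
                    ci=(float(x[s_i]), float(x[e_i])),
                    members=sub.reset_index(drop=True),
                    n_traits=len(traits),
                    traits=traits,
                    mean_pve=float(sub["pve"].mean()) if "pve" in sub else float("nan"),
                )
            )
    return hotspots


def hotspot_table(hotspots: list[QTLHotspot]) -> pd.DataFrame:
    """Summary table: hotspot id, CI (integer cM), member and trait counts."""
    rows = [
        {
            "hotspot": h.id,
            "chrom": h.chrom,
            "ci_cM": f"{int(round(h.ci[0]))}-{int(round(h.ci[1]))}",
            "n_mtas": len(h.members),
            "n_traits": h.n_traits,
            "traits": ", ".join(h.traits),
            "mean_pve": round(h.mean_pve, 2) if np.isfinite(h.mean_pve) else "",
        }
        for h in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=["hotspot", "chrom", "ci_cM", "n_mtas", "n_traits", "traits", "mean_pve"],
    )
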
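"""Minimal diagnostic plots (Manhattan, accuracy QQ)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(scan: pd.DataFrame, out_path: str, threshold: float = 3.0, title: str = "") -> None:
    """Simple per-chromosome Manhattan plot of -log10 p-values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0.0
    ticks, labels = [], []
    for i, c in enumerate(pd.unique(scan["chrom"])):
        sub = scan[scan["chrom"] == c]
        x = sub["cm"].to_numpy() + offset
        ax.scatter(x, sub["neg_log10_p"], s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + sub["cm"].mean())
        labels.append(str(c))
        offset += sub["cm"].max() + 5
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def accuracy_qq(accuracies: np.ndarray, out_path: str, title: str = "") -> None:
    """QQ plot of cross-validation accuracies against the normal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    fig, ax = plt.subplots(figsize=(4, 4))
    stats.probplot(np.asarray(accuracies), dist="norm", plot=ax)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
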
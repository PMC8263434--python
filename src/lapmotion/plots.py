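"""Optional figures: per-metric box plots, banded bar charts, PCA biplot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import CohortResult

GROUP_ORDER = ("novice", "intermediate", "expert")


def metric_boxplot(wide: pd.DataFrame, groups: pd.Series, metric: str, path: str | Path) -> None:
    """Box plot of one metric across the three experience groups."""
    fig, ax = plt.subplots(figsize=(4, 3))
    data = [wide.loc[groups == g, metric].dropna() for g in GROUP_ORDER]
    ax.boxplot(data, tick_labels=[g[0].upper() for g in GROUP_ORDER])
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def band_bars(fractions: pd.DataFrame, path: str | Path) -> None:
    """Stacked horizontal bars of band/zone fractions (rows = groups)."""
    fig, ax = plt.subplots(figsize=(6, 2 + 0.4 * len(fractions)))
    left = np.zeros(len(fractions))
    for col in fractions.columns:
        ax.barh(fractions.index, fractions[col], left=left, label=col)
        left += fractions[col].to_numpy()
    ax.set_xlabel("fraction")
    ax.legend(fontsize=7, ncol=min(len(fractions.columns), 5))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pca_biplot(result: CohortResult, groups: pd.Series, path: str | Path) -> None:
    """Score scatter (PC1 vs PC2) with loading arrows."""
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"novice": "tab:blue", "intermediate": "tab:orange", "expert": "tab:red"}
    for g in GROUP_ORDER:
        sel = groups.reindex(result.scores.index) == g
        ax.scatter(result.scores.loc[sel, "PC1"], result.scores.loc[sel, "PC2"],
                   s=18, label=g, color=colors[g])
    scale = float(np.abs(result.scores[["PC1", "PC2"]].to_numpy()).max())
    for metric, row in result.loadings.iterrows():
        ax.annotate(metric, (row["PC1"] * scale, row["PC2"] * scale), fontsize=6)
        ax.arrow(0, 0, row["PC1"] * scale * 0.9, row["PC2"] * scale * 0.9,
                 alpha=0.3, width=0.002 * scale)
    v = result.var_explained
    ax.set_xlabel(f"PC1 ({100 * v[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * v[1]:.0f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
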
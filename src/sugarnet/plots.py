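"""Optional figure emission from already-computed tables.

Tables are the contract; these plots are cosmetic summaries of them
(conservation dot-matrix, per-pathway abundance boxplots, correlation dot
plot). Everything renders with the non-interactive Agg backend.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_completeness_matrix", "plot_correlation_dots"]


def plot_completeness_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Dot-matrix of pathway conservation: dot size = gene count, color =
    completeness percentage, one row per species and column per pathway."""
    species = sorted(matrix["species"].unique())
    pathways = list(dict.fromkeys(matrix["pathway"]))
    fig, ax = plt.subplots(
        figsize=(0.55 * len(pathways) + 2.5, 0.5 * len(species) + 1.5)
    )
    for _, row in matrix.iterrows():
        x = pathways.index(row["pathway"])
        y = species.index(row["species"])
        size = 20 + 12 * row["gene_count"]
        sc = ax.scatter(
            x, y, s=size, c=[row["completeness_pct"]], cmap="viridis",
            vmin=0, vmax=100, edgecolors="k", linewidths=0.3,
        )
    ax.set_xticks(range(len(pathways)), pathways, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(species)), species, fontsize=8)
    ax.set_title("Pathway conservation (size: genes, color: completeness %)")
    fig.colorbar(sc, ax=ax, label="completeness %")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_dots(records: pd.DataFrame, path: str | Path) -> None:
    """Per-metabolite dot plot of passing gene-metabolite correlations;
    filled markers positive, open markers negative."""
    passing = records.loc[records["passes"]].copy()
    fig, ax = plt.subplots(figsize=(8, 4))
    if not passing.empty:
        metabolites = sorted(passing["metabolite"].unique())
        xpos = passing["metabolite"].map({m: i for i, m in enumerate(metabolites)})
        jitter = (np.arange(len(passing)) % 7 - 3) * 0.04
        pos = passing["pcc"] >= 0
        ax.scatter(xpos[pos] + jitter[pos.to_numpy()], passing.loc[pos, "pcc"],
                   c="tab:blue", s=18, label="positive")
        ax.scatter(xpos[~pos] + jitter[(~pos).to_numpy()], passing.loc[~pos, "pcc"],
                   facecolors="none", edgecolors="tab:red", s=18, label="negative")
        ax.set_xticks(range(len(metabolites)), metabolites, rotation=60,
                      ha="right", fontsize=7)
        ax.axhline(0.8, ls="--", lw=0.8, c="grey")
        ax.legend(fontsize=7)
    ax.set_ylabel("Pearson correlation")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title("Gene-metabolite correlations passing the screen")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
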
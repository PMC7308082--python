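"""Matplotlib figure helpers for sweep, landscape, and correspondence outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stability import FrequencyLandscape, SweepResult

__all__ = ["plot_sweep_heatmap", "plot_frequency_landscape", "plot_dotplot"]


def plot_sweep_heatmap(sweep: SweepResult, path: str) -> None:
    """Cluster count as a heatmap over (n_pcs, resolution)."""
    pivot = sweep.grid.pivot(index="resolution", columns="n_pcs",
                             values="n_clusters").sort_index(ascending=False)
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis",
                   extent=[min(pivot.columns), max(pivot.columns),
                           min(pivot.index), max(pivot.index)])
    ax.set_xlabel("number of leading PCs")
    ax.set_ylabel("Louvain resolution")
    fig.colorbar(im, ax=ax, label="clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_frequency_landscape(land: FrequencyLandscape, path: str) -> None:
    """Frequency of each cluster count, with local maxima marked."""
    xs = list(land.support)
    ys = [land.frequencies[x] for x in xs]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(xs, ys, "o-", color="tab:blue")
    for m in land.local_maxima:
        ax.axvline(m, color="tab:red", ls="--", alpha=0.5)
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("frequency over parameter grid")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dotplot(table: pd.DataFrame, path: str) -> None:
    """Correspondence dot plot: dot area = fraction of a query group assigned
    to a reference cluster."""
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * table.shape[1], 1 + 0.45 * table.shape[0])
    )
    for i, group in enumerate(table.index):
        for j, ref in enumerate(table.columns):
            frac = table.iloc[i, j]
            if frac > 0:
                ax.scatter(j, i, s=600 * frac, color="tab:blue", alpha=0.8)
    ax.set_xticks(np.arange(table.shape[1]), [str(c) for c in table.columns],
                  rotation=90)
    ax.set_yticks(np.arange(table.shape[0]), [str(r) for r in table.index])
    ax.set_xlabel("reference cluster")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
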
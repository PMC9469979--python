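"""Minimal figure writers: clustered heatmap, PCA scatter, dot plot.

These are convenience views of tables the pipeline already writes; all
statistics live in the TSV/JSON outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage


def heatmap(zvalues: pd.DataFrame, path: str | Path,
            sample_labels: pd.Series | None = None) -> None:
    """Clustered z-score heatmap (genes x samples, complete linkage)."""
    gz = linkage(zvalues.to_numpy(), method="complete")
    sz = linkage(zvalues.to_numpy().T, method="complete")
    g_order = dendrogram(gz, no_plot=True)["leaves"]
    s_order = dendrogram(sz, no_plot=True)["leaves"]
    data = zvalues.iloc[g_order, s_order]
    fig, ax = plt.subplots(figsize=(8, 10))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3)
    ax.set_xticks(range(data.shape[1]))
    names = data.columns
    if sample_labels is not None:
        names = [f"{s} ({sample_labels[s]})" for s in data.columns]
    ax.set_xticklabels(names, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(coords: pd.DataFrame, evr: np.ndarray, path: str | Path,
                labels: pd.Series | None = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels is None:
        ax.scatter(coords["PC1"], coords["PC2"])
    else:
        for lab in sorted(labels.unique()):
            m = labels.loc[coords.index] == lab
            ax.scatter(coords.loc[m, "PC1"], coords.loc[m, "PC2"], label=lab)
        ax.legend()
    ax.set_xlabel(f"Dim.1 ({100 * evr[0]:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"Dim.2 ({100 * evr[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_dotplot(results: pd.DataFrame, path: str | Path) -> None:
    """Dot plot of enrichment results: -log10(p) vs set, dot size =
    overlap count."""
    df = results.sort_values("p")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    y = np.arange(len(df))[::-1]
    ax.scatter(-np.log10(np.maximum(df["p"], 1e-300)), y,
               s=10 * df["overlap"].clip(lower=1))
    ax.set_yticks(y)
    ax.set_yticklabels(df.index, fontsize=7)
    ax.set_xlabel("-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
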
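"""Export-only plots: signature profiles, exposures, match heatmaps,
silhouettes. These are presentation artifacts; nothing downstream
depends on them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_CLASS_COLORS = {
    "C>A": "#03BCEE",
    "C>G": "#010101",
    "C>T": "#E32926",
    "T>A": "#CAC9C9",
    "T>C": "#A1CE63",
    "T>G": "#EBC6C4",
}


def _class_of(label: str) -> str:
    for cls in _CLASS_COLORS:
        if cls in label.replace(" ", ""):
            return cls
    return "C>A"


def plot_signature_profiles(signatures: pd.DataFrame, path: str | Path) -> None:
    """One barplot panel per signature, bars colored by substitution class."""
    k = signatures.shape[1]
    fig, axes = plt.subplots(k, 1, figsize=(12, 2.2 * k), squeeze=False, sharex=True)
    colors = [_CLASS_COLORS[_class_of(str(l))] for l in signatures.index]
    x = np.arange(len(signatures.index))
    for j, name in enumerate(signatures.columns):
        ax = axes[j, 0]
        ax.bar(x, signatures[name].to_numpy(), color=colors, width=0.8)
        ax.set_ylabel(name, fontsize=8)
        ax.set_xlim(-1, len(x))
    axes[-1, 0].set_xticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_exposures(exposures: pd.DataFrame, path: str | Path, relative: bool = False) -> None:
    """Stacked per-sample exposure barplot (absolute or relative)."""
    E = exposures
    if relative:
        E = E / E.sum(axis=0)
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * E.shape[1]), 4))
    bottom = np.zeros(E.shape[1])
    x = np.arange(E.shape[1])
    for name in E.index:
        vals = E.loc[name].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=str(name))
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(E.columns, rotation=90, fontsize=6)
    ax.set_ylabel("relative activity" if relative else "mutations")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_match_heatmap(distance_matrix: pd.DataFrame, path: str | Path) -> None:
    """Cosine-distance heatmap between two signature sets (dark = close)."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * distance_matrix.shape[1],
                                    1 + 0.6 * distance_matrix.shape[0]))
    im = ax.imshow(distance_matrix.to_numpy(), cmap="viridis_r", vmin=0, vmax=1)
    ax.set_xticks(range(distance_matrix.shape[1]))
    ax.set_xticklabels(distance_matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(distance_matrix.shape[0]))
    ax.set_yticklabels(distance_matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="cosine distance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_silhouettes(assignments, widths, path: str | Path) -> None:
    """Horizontal silhouette plot grouped by cluster."""
    assignments = np.asarray(assignments)
    widths = np.asarray(widths)
    order = np.lexsort((-widths, assignments))
    fig, ax = plt.subplots(figsize=(6, max(3, 0.05 * len(widths))))
    cmap = plt.get_cmap("tab10")
    ax.barh(np.arange(len(widths)), widths[order],
            color=[cmap(a % 10) for a in assignments[order]])
    ax.set_xlabel("silhouette width")
    ax.set_xlim(-1, 1)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
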
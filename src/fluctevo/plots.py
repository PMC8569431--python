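"""Minimal figures: relative-growth scatter and PCA score plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_strategy_scatter", "plot_pca_scores"]

_STRATEGY_COLORS = {
    "generalist": "#e8a070",
    "specialist_43": "#c23b22",
    "specialist_15": "#3b6fc2",
    "not_significant": "#9a9a9a",
}


def plot_strategy_scatter(strategy_table: pd.DataFrame, path) -> Path:
    """Relative growth at 15 degC (x) vs 43 degC (y), coloured by strategy."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, grp in strategy_table.groupby("category"):
        ax.scatter(
            grp["ratio_15"], grp["ratio_43"],
            color=_STRATEGY_COLORS.get(cat, "black"), label=cat, s=30,
        )
    ax.axhline(1.0, color="grey", lw=0.8, ls=":")
    ax.axvline(1.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("relative growth rate at 15 °C")
    ax.set_ylabel("relative growth rate at 43 °C")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_pca_scores(scores: pd.DataFrame, meta: pd.DataFrame, path, hue: str = "temperature_C") -> Path:
    """First two component scores coloured by a metadata column."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    merged = scores.join(meta[hue])
    for value, grp in merged.groupby(hue):
        ax.scatter(grp.iloc[:, 0], grp.iloc[:, 1], label=f"{hue}={value}", s=14, alpha=0.8)
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
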
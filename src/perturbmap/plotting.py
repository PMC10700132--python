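"""Simple diagnostic plots for map results and abundance tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .regmap import PerturbationMapResults
from .screen_stats import AbundanceResult

__all__ = ["plot_strength_heatmap", "plot_abundance_ranks"]


def plot_strength_heatmap(results: PerturbationMapResults, ax=None):
    """Module × programme strength as a signed heatmap (red +, blue −)."""
    s = results.strength.astype(float)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.6 * s.shape[1], 1.0 + 0.4 * s.shape[0]))
    vmax = np.nanmax(np.abs(s.to_numpy())) or 1.0
    im = ax.imshow(s.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(s.shape[1]), [str(c) for c in s.columns])
    ax.set_yticks(range(s.shape[0]), [f"M{i}" for i in s.index])
    ax.set_xlabel("gene programme")
    ax.set_ylabel("TF module")
    ax.figure.colorbar(im, ax=ax, label="mean log2FC")
    return ax


def plot_abundance_ranks(result: AbundanceResult, ax=None, highlight: float = 0.0):
    """Targets ranked by log2 cell-yield ratio vs NTC (waterfall plot)."""
    table = result.table.sort_values("log2_ratio_vs_ntc")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    vals = table["log2_ratio_vs_ntc"].to_numpy()
    colors = np.where(vals >= highlight, "#c0392b", "#2980b9")
    ax.bar(range(len(vals)), vals, color=colors, width=1.0)
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("perturbation rank")
    ax.set_ylabel("log2 ratio vs NTC")
    return ax
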
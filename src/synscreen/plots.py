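"""Summary figures: IC50 strip plot and CI box plot with guide lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .panel_screen import PanelResult, fits_table, ci_summary_table

__all__ = ["ic50_strip_plot", "ci_box_plot"]


def ic50_strip_plot(panel: PanelResult, path, guides=(2.0, 10.0)) -> None:
    """Per-condition IC50 strip plot on a log scale with threshold guides."""
    df = fits_table(panel)
    df = df[df["ic50_class"] != ""]
    conds = sorted(df["condition"].unique())
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * max(len(conds), 1), 4))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, cond in enumerate(conds):
        vals = df.loc[df["condition"] == cond, "ic50_reported_uM"]
        x = i + rng.uniform(-0.15, 0.15, size=len(vals))
        ax.scatter(x, vals, s=18, alpha=0.8)
    for g in guides:
        ax.axhline(g, ls=":", c="grey", lw=1)
    ax.set_yscale("log")
    ax.set_xticks(range(len(conds)), conds, rotation=30, ha="right")
    ax.set_ylabel("IC50 (μM)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ci_box_plot(panel: PanelResult, path, guides=(0.8, 1.2)) -> None:
    """Per-ratio box plot of per-line median CI with additivity-band guides."""
    df = ci_summary_table(panel)
    df = df.dropna(subset=["median_ci"])
    ratios = sorted(df["ratio"].unique())
    data = [df.loc[df["ratio"] == r, "median_ci"].to_numpy() for r in ratios]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * max(len(ratios), 1), 4))
    if data:
        ax.boxplot(data, tick_labels=ratios)
    for g in guides:
        ax.axhline(g, ls=":", c="grey", lw=1)
    ax.set_ylabel("combination index (median over E50-E80)")
    ax.set_xlabel("PD:AZ ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
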
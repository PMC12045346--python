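"""Minimal renderings of the pipeline's data tables.

These are convenience views (volcano, Kaplan-Meier, nomogram chart); all
quantitative output lives in the TSV/JSON artifacts the pipeline writes.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .nomogram import NomogramSpec

__all__ = ["volcano_plot", "km_plot", "nomogram_chart"]


def volcano_plot(dmr_table: pd.DataFrame, comparison: str, ax=None):
    """Mean MHL difference vs -log10 p for one state comparison."""
    sub = dmr_table[dmr_table["comparison"] == comparison]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sig = sub["significant"].astype(bool)
    ax.scatter(sub.loc[~sig, "mean_diff"], sub.loc[~sig, "neg_log10_p"],
               s=8, c="grey", alpha=0.6)
    colors = np.where(sub.loc[sig, "mean_diff"] > 0, "firebrick", "steelblue")
    ax.scatter(sub.loc[sig, "mean_diff"], sub.loc[sig, "neg_log10_p"],
               s=10, c=colors)
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, c="k")
    ax.set_xlabel("mean MHL difference")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(comparison)
    return ax


def km_plot(km: dict, ax=None):
    """Step curves for the two risk groups with the log-rank p annotated."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for g in km["groups"]:
        curve = km["curves"][g]
        ax.step(curve.index, curve.values, where="post", label=str(g))
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.legend(title=f"log-rank p = {km['logrank_p']:.2g}")
    return ax


def nomogram_chart(spec: NomogramSpec, ax=None):
    """Static nomogram: one points axis per predictor plus a total-points
    axis annotated with horizon survival probabilities."""
    n = len(spec.predictors)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 1.2 * (n + 2)))
    ax.set_xlim(-5, 105)
    ax.set_ylim(-1.5, n + 0.5)
    ax.axis("off")
    ax.hlines(n, 0, 100, lw=1)
    for p in range(0, 101, 10):
        ax.text(p, n + 0.15, str(p), ha="center", fontsize=7)
    ax.text(-4, n, "Points", ha="right", va="center", fontsize=8)
    for i, pred in enumerate(spec.predictors):
        y = n - 1 - i
        lo, hi = spec.ranges[pred]
        p_lo, p_hi = spec.points(pred, lo), spec.points(pred, hi)
        ax.hlines(y, min(p_lo, p_hi), max(p_lo, p_hi), lw=1)
        for x, pts in ((lo, p_lo), (hi, p_hi)):
            ax.plot([pts], [y], "k|", ms=8)
            ax.text(pts, y - 0.3, f"{x:.3g}", ha="center", fontsize=7)
        ax.text(-4, y, pred, ha="right", va="center", fontsize=8)
    # total points axis with horizon survival annotations
    max_total = sum(max(spec.points(p, spec.ranges[p][0]),
                        spec.points(p, spec.ranges[p][1]))
                    for p in spec.predictors)
    ax.hlines(-1, 0, 100, lw=1)
    ax.text(-4, -1, "Total points", ha="right", va="center", fontsize=8)
    for frac in np.linspace(0, 1, 6):
        tp = frac * max_total
        lp = spec.lp_from_points(tp)
        labels = [f"S({int(t)}m)={spec.baseline_at(t) ** np.exp(lp - spec.mean_lp):.2f}"
                  for t in spec.horizons]
        ax.plot([frac * 100], [-1], "k|", ms=8)
        ax.text(frac * 100, -1.35, f"{tp:.0f}\n" + "\n".join(labels),
                ha="center", va="top", fontsize=6)
    return ax
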
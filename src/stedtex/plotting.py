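"""Notched box plots of per-block features, one panel per feature.

Notches span median +/- 2 SE(median) (bootstrap estimate); the median is
drawn as a thin red line.
"""

from __future__ import annotations

import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import GroupComparisonResult


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def notched_box_figure(table: pd.DataFrame, results: list[GroupComparisonResult],
                       group_a: str, group_b: str,
                       features: tuple[str, ...]) -> plt.Figure:
    by_name = {r.feature_name: r for r in results}
    feats = [f for f in features if f in by_name]
    ncol = min(4, len(feats))
    nrow = math.ceil(len(feats) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.2 * nrow), squeeze=False)
    for ax in axes.ravel()[len(feats):]:
        ax.set_visible(False)
    for ax, feat in zip(axes.ravel(), feats):
        r = by_name[feat]
        data = []
        for g in (group_a, group_b):
            vals = table.loc[table["group"] == g, feat].to_numpy(dtype=float)
            data.append(vals[np.isfinite(vals)])
        ax.boxplot(
            data, notch=True, tick_labels=[group_a, group_b], showfliers=False,
            medianprops={"color": "red", "linewidth": 1.0},
            conf_intervals=[list(r.notch_a), list(r.notch_b)],
        )
        ax.set_title(f"{feat}  ({_stars(r.p_value)})", fontsize=9)
        ax.tick_params(labelsize=8)
    fig.tight_layout()
    return fig
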
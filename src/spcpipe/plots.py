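"""Convenience matplotlib views: volcano, MDP strip plot, clustered heatmap.

Correctness lives in the tabular outputs; these are presentation helpers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign
from .differential import TFoldConfig
from .enrich import ClusterLayout, zscore_rows


def volcano(classified: pd.DataFrame, cfg: TFoldConfig | None = None, ax=None):
    """Four-class volcano: log2FC vs -log2 p, coloured by filter outcome."""
    import matplotlib.pyplot as plt

    cfg = cfg or TFoldConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    neglogp = -np.log2(np.maximum(classified["p"], 1e-300))
    for cls in ("red", "green", "orange", "blue"):
        m = classified["volcano_class"] == cls
        ax.scatter(classified.loc[m, "log2fc"], neglogp[m], s=6, c=cls, label=cls, alpha=0.6)
    ax.axvline(cfg.fc_cutoff, ls="--", lw=0.5, c="grey")
    ax.axvline(-cfg.fc_cutoff, ls="--", lw=0.5, c="grey")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log2 t-test p")
    ax.legend(fontsize=7)
    return ax


def mdp_plot(scores: pd.Series, design: StudyDesign, ax=None):
    """Per-group strip plot of sample MDP scores with group medians."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)
    for i, g in enumerate(design.group_names):
        vals = scores[list(design.samples_of(g))].to_numpy()
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.scatter(x, vals, s=18)
        ax.hlines(np.median(vals), i - 0.25, i + 0.25, color="black", lw=1.5)
    ax.set_xticks(range(len(design.group_names)), design.group_names)
    ax.set_ylabel("molecular degree of perturbation")
    return ax


def heatmap(matrix: pd.DataFrame, layout: ClusterLayout, ax=None):
    """Row-z-scored heatmap with rows/columns in clustered leaf order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    z = zscore_rows(matrix).loc[layout.row_order, layout.col_order]
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(layout.col_order)), layout.col_order, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.figure.colorbar(im, ax=ax, label="row z-score")
    return ax
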
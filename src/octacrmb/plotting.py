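"""Convenience plots: correlation heatmap and per-biomarker violins."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import CRMB_NAMES
from .stats import CorrelationMatrix


def correlation_heatmap(corr: CorrelationMatrix, order=None, path=None):
    """Kendall-tau heatmap; insignificant cells are marked with a cross."""
    idx = np.arange(len(corr.variables)) if order is None else np.asarray(order)
    tau = corr.tau[np.ix_(idx, idx)]
    names = [corr.variables[i] for i in idx]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(tau, vmin=-1, vmax=1, cmap="RdBu")
    for i in range(len(idx)):
        for j in range(len(idx)):
            if i != j and not corr.significant[idx[i], idx[j]]:
                ax.plot(j, i, "x", color="0.4", ms=6)
    ax.set_xticks(range(len(names)), names, rotation=90)
    ax.set_yticks(range(len(names)), names)
    fig.colorbar(im, ax=ax, label="Kendall tau")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def crmb_violins(table: pd.DataFrame, group_col: str = "group", path=None):
    """Per-biomarker violin plots split by group."""
    vars_ = [v for v in CRMB_NAMES if v in table.columns]
    groups = list(pd.unique(table[group_col]))
    fig, axes = plt.subplots(3, 4, figsize=(12, 8))
    for ax, v in zip(axes.ravel(), vars_):
        data = [table.loc[table[group_col] == g, v].dropna() for g in groups]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks([1, 2], groups)
        ax.set_title(v)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
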
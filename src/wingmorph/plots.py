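"""Minimal diagnostic plots: per-specimen PGMP composition bars and
consistency-by-threshold lines. Aesthetics are deliberately plain."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_pgmp(pgmp: pd.DataFrame, labels: pd.Series | None = None,
              ax: plt.Axes | None = None) -> plt.Figure:
    """Stacked-bar PGMP composition, one bar per specimen.

    Specimens are ordered by prior group (when ``labels`` is given) and
    by their own-group probability within it.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(pgmp) * 0.04), 3))
    table = pgmp.copy()
    if labels is not None:
        order = pd.DataFrame({"lab": labels.loc[table.index]})
        order["own"] = [table.loc[i, str(l)] for i, l in labels.items()]
        table = table.loc[order.sort_values(["lab", "own"]).index]
    bottom = np.zeros(len(table))
    for col in table.columns:
        ax.bar(range(len(table)), table[col].to_numpy(), width=1.0,
               bottom=bottom, label=str(col))
    ax.set_xlim(-0.5, len(table) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("PGMP")
    ax.set_xlabel("specimens")
    ax.legend(fontsize="small", ncol=min(len(table.columns), 5))
    return ax.figure


def plot_consistency(consistency: pd.DataFrame,
                     ax: plt.Axes | None = None) -> plt.Figure:
    """Consistency rate per prior group across assignment thresholds.

    Expects the per-group table from
    :func:`wingmorph.assignment.consistency_by_threshold` (rows = prior
    groups, columns = thresholds).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = range(len(consistency.columns))
    for group, row in consistency.iterrows():
        ax.plot(list(x), row.to_numpy(), marker="o", label=str(group))
    ax.set_xticks(list(x), [str(c) for c in consistency.columns])
    ax.set_xlabel("PGMP threshold")
    ax.set_ylabel("proportion consistently assigned")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize="small")
    return ax.figure
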
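"""Minimal summary plots (per-role / per-pair bar charts with error bars)."""

from __future__ import annotations

import pandas as pd


def bar_summary(table: pd.DataFrame, value: str, unit_col: str, ax=None):
    """Grouped bar chart of mean +/- sd of ``value`` per (unit, condition)."""
    import matplotlib.pyplot as plt

    agg = table.groupby([unit_col, "condition"], sort=True, observed=True)[value].agg(
        ["mean", "std"]
    )
    units = agg.index.get_level_values(0).unique()
    conds = agg.index.get_level_values(1).unique()
    if ax is None:
        _, ax = plt.subplots(figsize=(1.8 * len(units) + 2, 4))
    width = 0.8 / len(conds)
    for j, cond in enumerate(conds):
        means = [agg.loc[(u, cond), "mean"] if (u, cond) in agg.index else float("nan")
                 for u in units]
        sds = [agg.loc[(u, cond), "std"] if (u, cond) in agg.index else float("nan")
               for u in units]
        xs = [i + (j - (len(conds) - 1) / 2) * width for i in range(len(units))]
        ax.bar(xs, means, width=width, yerr=sds, capsize=2, label=str(cond))
    ax.set_xticks(range(len(units)))
    ax.set_xticklabels(units)
    ax.set_ylabel(value)
    ax.legend(fontsize=8)
    return ax
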
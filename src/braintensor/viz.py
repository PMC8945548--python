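"""Plotting helpers (matplotlib): ROI violin plots and fit diagnostics."""

from __future__ import annotations

import numpy as np

from .roistats import ROIStatsTable


def plot_roi_violins(table: ROIStatsTable, ax=None, alphas=(0.05, 0.001)):
    """Violin plot of per-ROI normalized map values.

    An asterisk marks ROIs significant versus their containing region at the
    first alpha after correction; a double asterisk at the second.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(table.values), 1) + 1, 4))
    names = list(table.values)
    if not names:
        raise ValueError("table carries no ROI value distributions")
    data = [np.asarray(table.values[n]) for n in names]
    ax.violinplot(data, showmedians=True)
    ax.axhline(0.0, color="0.6", lw=0.8, zorder=0)
    top = max(float(np.max(d)) for d in data)
    for i, name in enumerate(names, start=1):
        row = table.row(name)
        mark = ""
        if row.get(f"significant_at_{alphas[1]:g}", False):
            mark = "**"
        elif row.get(f"significant_at_{alphas[0]:g}", False):
            mark = "*"
        if mark:
            ax.text(i, top * 1.05, mark, ha="center", fontsize=12)
    ax.set_xticks(range(1, len(names) + 1), names, rotation=45, ha="right")
    ax.set_ylabel("normalized subcortical map value\n(fraction of cortical strength)")
    return ax


def plot_fit_history(decomposition, ax=None):
    """Relative reconstruction error as a function of rank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hist = decomposition.fit_history
    ax.plot(range(1, len(hist) + 1), hist, marker="o")
    ax.set_xlabel("rank")
    ax.set_ylabel("relative reconstruction error")
    return ax
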
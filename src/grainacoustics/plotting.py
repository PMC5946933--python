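"""Diagnostic plots: O2 decline per treatment and activity vs oxygen."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hermetic import add_depletion

__all__ = ["plot_oxygen_vs_day", "plot_activity_vs_oxygen"]


def plot_oxygen_vs_day(records: pd.DataFrame, ax=None):
    """Mean residual O2 (%) against storage day, one line per treatment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for tid, group in records.groupby("treatment_id", sort=False):
        means = group.groupby("day")["residual_o2_pct"].mean()
        ax.plot(means.index, means.values, marker="o", ms=3, label=tid)
    ax.set_xlabel("Storage time (d)")
    ax.set_ylabel("Residual O$_2$ (%)")
    ax.legend(fontsize=8)
    return ax


def plot_activity_vs_oxygen(records: pd.DataFrame, measure: str = "rb", ax=None):
    """Per-insect Log10(x+1) activity (or raw nb) against residual O2.

    Rate measures are shown as Log10(measure/n_insects + 1); impulses per
    burst (nb) is plotted directly on its natural 3-6 scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = add_depletion(records).dropna(subset=[measure])
    for tid, group in data.groupby("treatment_id", sort=False):
        if measure == "nb":
            y = group[measure]
            ylabel = "No. impulses per burst"
        else:
            y = np.log10(group[measure] / group["n_insects"] + 1.0)
            ylabel = f"Log$_{{10}}$({measure}/N$_t$ + 1)"
        ax.scatter(group["residual_o2_pct"], y, s=12, label=tid)
    ax.set_xlabel("Residual O$_2$ (%)")
    ax.set_ylabel(ylabel)
    ax.invert_xaxis()  # time runs left to right as oxygen depletes
    ax.legend(fontsize=8)
    return ax
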
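"""Figure helpers: richness bars, ordination scatter, betaNTI histogram.

The neutral-model occupancy plot lives on
:meth:`mycoassembly.neutral.SloanNeutralResults.plot`; the 2DP heat matrix is
written as TSV by the preference stage and renders directly with seaborn or
pheatmap-style tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assembly import BNTI_THRESHOLD


def plot_richness_by_group(richness: pd.Series, groups: pd.Series, letters=None, ax=None):
    """Mean +- SE richness bars per group, annotated with a letters display."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stats = richness.groupby(groups).agg(["mean", "sem", "count"])
    x = np.arange(len(stats))
    ax.bar(x, stats["mean"], yerr=stats["sem"], capsize=3, color="0.7", edgecolor="0.2")
    ax.set_xticks(x, stats.index, rotation=30, ha="right")
    ax.set_ylabel("OTU richness")
    if letters:
        for i, g in enumerate(stats.index):
            ax.text(i, stats.loc[g, "mean"] + stats.loc[g, "sem"], letters.get(g, ""),
                    ha="center", va="bottom")
    return ax


def plot_ordination(ordination, groups: pd.Series, ax=None):
    """First two ordination axes, colored by group, with group centroids."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = ordination.coordinates.iloc[:, :2]
    for g, sub in coords.groupby(groups.reindex(coords.index)):
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=18, label=str(g))
        ax.scatter(sub.iloc[:, 0].mean(), sub.iloc[:, 1].mean(), marker="x", s=60,
                   color=ax.collections[-1].get_facecolor()[0])
    var = ordination.proportion_explained
    ax.set_xlabel(f"Axis 1 ({100 * var[0]:.1f}%)")
    ax.set_ylabel(f"Axis 2 ({100 * var[1]:.1f}%)" if len(var) > 1 else "Axis 2")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_bnti_distribution(bnti_values, ax=None):
    """Histogram of pairwise betaNTI with the +-2 stochastic band marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = np.asarray(bnti_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    ax.hist(vals, bins=30, color="0.7", edgecolor="0.3")
    for edge in (-BNTI_THRESHOLD, BNTI_THRESHOLD):
        ax.axvline(edge, color="tab:red", ls="--", lw=1)
    ax.set_xlabel(r"$\beta$NTI")
    ax.set_ylabel("sample pairs")
    return ax
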
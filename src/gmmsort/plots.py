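"""Diagnostic plots for sorting results (matplotlib, non-interactive safe)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_clusters", "plot_feature_scores", "plot_feature_density"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_clusters(results, dims=(0, 1), ax=None):
    """Scatter of two selected feature dimensions colored by cluster label."""
    ax = _get_ax(ax)
    x = results.selected_features.values
    i, j = dims
    for c in range(1, results.n_clusters + 1):
        m = results.labels == c
        ax.scatter(x[m, i], x[m, j], s=4, label=f"cluster {c}")
    ids = results.selected_features.feature_ids
    ax.set_xlabel(ids[i].label)
    ax.set_ylabel(ids[j].label)
    ax.legend(markerscale=3, fontsize=8)
    return ax


def plot_feature_scores(results, ax=None):
    """Separability score per candidate feature, selected ones highlighted."""
    ax = _get_ax(ax)
    s = results.scores.scores
    ax.bar(np.arange(len(s)), s, color="0.7")
    ax.set_xlabel("candidate feature")
    ax.set_ylabel(f"{results.scores.metric} score")
    return ax


def plot_feature_density(model, data, ax=None, bins=60):
    """Histogram of one feature with the fitted mixture density overlaid."""
    ax = _get_ax(ax)
    data = np.asarray(data, dtype=float).ravel()
    ax.hist(data, bins=bins, density=True, color="0.8")
    grid = np.linspace(data.min(), data.max(), 400)
    ax.plot(grid, model.density(grid), "k-", lw=1.5)
    ax.set_ylabel("density")
    return ax
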
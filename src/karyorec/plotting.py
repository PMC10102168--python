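"""Plot helpers: co-occurrence heat maps, gap curves, increment plots.

These are thin matplotlib wrappers around the pipeline's data tables; the
numbers, not the figures, are the contract.
"""

from __future__ import annotations

import numpy as np

from .karyotype_inference import GapProfile


def heatmap(C: np.ndarray, labels: np.ndarray | None = None, ax=None,
            quantile_norm: bool = True):
    """Unit × unit heat map, cluster-ordered, grey scale.

    With ``quantile_norm`` the counts are rank-transformed so that darkness
    proportions are comparable across heat maps of different scales.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    M = np.asarray(C, dtype=float)
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
        M = M[np.ix_(order, order)]
    if quantile_norm and M.size:
        flat = M.ravel()
        ranks = np.searchsorted(np.sort(flat), flat, side="right")
        M = (ranks / len(flat)).reshape(M.shape)
    ax.imshow(1.0 - M, cmap="gray", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def gap_curves(profiles: list[GapProfile], mean_prof: GapProfile | None = None,
               selected_mean: GapProfile | None = None, ax=None):
    """All samples' gap curves (grey), overall mean (black), selected-samples
    mean (blue)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.ks, p.gap, color="0.8", lw=0.6, zorder=1)
    if mean_prof is not None:
        ax.plot(mean_prof.ks, mean_prof.gap, "ko-", ms=3, zorder=2,
                label="mean")
    if selected_mean is not None:
        ax.plot(selected_mean.ks, selected_mean.gap, "bo-", ms=3, zorder=3,
                label="mean of best")
    ax.set_xlabel("k (number of clusters)")
    ax.set_ylabel("gap statistic")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def increment_plot(table, ax=None, highlight_k: tuple[int, int] = (9, 10)):
    """Fig-11-style increment transition plot from increment_plot_data."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for run, df in table.groupby("run"):
        ax.plot(df["k"], df["offset_increment"], "o-", ms=3, label=str(run))
    for k in highlight_k:
        ax.axvline(k, color="0.5", ls="--", lw=0.8)
    ax.set_xlabel("k")
    ax.set_ylabel("gap increment (offset per run)")
    ax.legend(fontsize=7)
    return ax
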
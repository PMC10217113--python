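"""Optional matplotlib views: TDS curves, similarity histograms, r-vs-R lines.

These are presentation side-outputs; nothing downstream depends on them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .rscan import CorrelationGrid, SimilaritySet
from .trial import DominanceCurve


def plot_tds_curve(curve: DominanceCurve, labels: Sequence[str], ax=None):
    """Step plot of dominance proportions over normalized time (a TDS curve)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = curve.breakpoints
    for i, label in enumerate(labels):
        y = np.append(curve.values[:, i], curve.values[-1, i])
        ax.step(t, y, where="post", label=label)
    ax.set_xlabel("normalized time")
    ax.set_ylabel("dominance proportion")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small", ncol=3)
    return ax


def plot_similarity_histograms(sets: Sequence[SimilaritySet], binwidth: float = 0.025):
    """Histogram of each C_R (bin width 0.025 by default), one panel per R."""
    import matplotlib.pyplot as plt

    n = len(sets)
    ncols = min(n, 3)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax, C in zip(axes.flat, sets):
        v = C.values()
        lo = np.floor(v.min() / binwidth) * binwidth
        hi = np.ceil(v.max() / binwidth) * binwidth + binwidth / 2
        ax.hist(v, bins=np.arange(lo, hi, binwidth), edgecolor="black")
        ax.set_title(f"R = {C.R}")
        ax.set_xlabel("similarity to centroid")
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig


def plot_correlation_lines(grid: CorrelationGrid, ax=None):
    """Lines of r(R1, R2) versus R1, one line per R2."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for j, R2 in enumerate(grid.R_values):
        ax.plot(grid.R_values, grid.r[:, j], marker="o", label=f"$R_2$={R2}")
    ax.set_xlabel("$R_1$")
    ax.set_ylabel("correlation of similarity sets")
    ax.set_xscale("log")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize="small")
    return ax
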
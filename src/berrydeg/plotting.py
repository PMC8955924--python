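"""Optional matplotlib figures: replicate scatter and ratio-interval bars."""

from __future__ import annotations

import numpy as np

from .deg_ratio import RatioHistogram


def replicate_scatter(expr, sample_a: str, sample_b: str, ax=None):
    """ln-ln point cloud of two replicate columns with the fitted line.

    Cells where either replicate is zero are dropped (ln undefined).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = expr[sample_a].to_numpy(float)
    y = expr[sample_b].to_numpy(float)
    keep = (x > 0) & (y > 0)
    lx, ly = np.log(x[keep]), np.log(y[keep])
    ax.plot(lx, ly, ".", ms=2, alpha=0.4)
    if len(lx) >= 2 and np.ptp(lx) > 0:
        b, a = np.polyfit(lx, ly, 1)
        grid = np.linspace(lx.min(), lx.max(), 2)
        ax.plot(grid, a + b * grid, "r-", lw=1)
    ax.set_xlabel(f"ln RPKM ({sample_a})")
    ax.set_ylabel(f"ln RPKM ({sample_b})")
    return ax


def ratio_bars(hist: RatioHistogram, ax=None):
    """Bar plot of transcript counts per signed-ratio interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bins = hist.bins
    ax.bar(range(len(bins)), bins["count"])
    ax.set_xticks(range(len(bins)), bins["label"], rotation=45, ha="right")
    ax.set_ylabel("transcripts")
    ax.set_xlabel("signed ratio interval")
    return ax
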
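"""Diagnostic plot: binned counts, fitted trend curve, and marked indices."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .binning import BinnedDistances
from .curve import InflectionIndices, TrendCurve


def plot_trend(
    dist: BinnedDistances,
    curve: TrendCurve,
    indices: Optional[InflectionIndices] = None,
    path: "str | Path | None" = None,
    ax=None,
):
    """Plot binned counts with the fitted curve and any detected indices.

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    if ax is None and path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar(dist.midpoints, dist.counts, width=dist.bin_width * 0.9,
           color="#9ecae1", label="participants per bin")
    x = np.linspace(curve.domain_lo, curve.domain_hi, 400)
    ax.plot(x, curve(x), color="#de2d26", lw=2, label=f"trend (degree {curve.degree})")
    if indices is not None:
        for est, label, color in ((indices.pwd, "PWD", "#31a354"),
                                  (indices.tld, "TLD", "#756bb1")):
            if est is not None:
                ax.axvline(est.root, color=color, ls="--",
                           label=f"{label} {est.bin_lo:.0f}-{est.bin_hi:.0f} m")
    ax.set_xlabel("distance to nearest provider (m)")
    ax.set_ylabel("participants")
    ax.set_xlim(curve.domain_lo, curve.domain_hi)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
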
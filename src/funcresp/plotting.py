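"""Curve-plus-band figures for treatment comparisons."""

from __future__ import annotations

import numpy as np

from .bootstrap import BootstrapResult, curve_band
from .core import rogers_expected


def plot_bands(results: dict[str, BootstrapResult], ax=None, grid_step: float = 1.0):
    """Plot point-estimate curves with shaded 95% bootstrap bands.

    ``results`` maps a label (e.g. the distribution treatment) to a
    bootstrap result; all are drawn on a shared density grid.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, bs in results.items():
        lo, hi = bs.density_range
        grid = np.arange(lo, hi + 0.5 * grid_step, grid_step, dtype=float)
        band_lo, band_hi = curve_band(bs, grid)
        curve = rogers_expected(bs.point.attack_rate_hat, bs.point.handling_time_hat, bs.duration, grid)
        (line,) = ax.plot(grid, curve, label=label)
        ax.fill_between(grid, band_lo, band_hi, alpha=0.3, color=line.get_color(), linewidth=0)
    ax.set_xlabel("initial prey density")
    ax.set_ylabel("prey killed per exposure")
    ax.legend()
    return ax
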
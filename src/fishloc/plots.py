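"""Figure helpers: box plots (whiskers at data extremes) and radial curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .stats import radial_distribution

__all__ = ["plot_boxes", "plot_radial"]


def plot_boxes(groups: dict, path, ylabel: str = "") -> None:
    """Box plots for named value groups.

    Whiskers span the full data range (highest and lowest points), the box
    the inter-quartile range, the middle line the median — no outlier
    trimming.
    """
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.6))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()),
               whis=(0, 100), showfliers=False)
    ax.set_ylabel(ylabel)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=140)
    plt.close(fig)


def plot_radial(groups: dict, path, bins: int = 10) -> None:
    """Relative-frequency polygons and ECDFs of fractional radius (0 =
    nuclear periphery, 1 = centre) for named groups."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.4))
    for label, values in groups.items():
        if len(values) == 0:
            continue
        rd = radial_distribution(values, bins=bins)
        mids = 0.5 * (rd.bin_edges[:-1] + rd.bin_edges[1:])
        ax1.plot(mids, rd.frequency, marker="o", ms=3, label=label)
        ax2.step(np.concatenate([[0.0], rd.ecdf_x, [1.0]]),
                 np.concatenate([[0.0], rd.ecdf_y, [1.0]]),
                 where="post", label=label)
    ax1.set_xlabel("fractional radius")
    ax1.set_ylabel("relative frequency")
    ax2.set_xlabel("fractional radius")
    ax2.set_ylabel("ECDF")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=140)
    plt.close(fig)
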
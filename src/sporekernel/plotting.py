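"""Static figures: per-animal densities with an across-animal band, and the
overall cumulative dispersal curve with its quantile rules."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless; figures are written, never shown
import matplotlib.pyplot as plt  # noqa: E402


def plot_density(results, ax=None, bin_width: float = 25.0, level: float = 0.50):
    """Per-animal binned densities (thin lines), their mean (thick) and the
    central-``level`` across-animal band, on a log probability axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for a, k in sorted(results.animal_kernels.items()):
        d = k.binned_density(bin_width)
        ax.plot(d["bin_center"], d["probability"], lw=0.8, alpha=0.7, label=a)
    if results.n_animals >= 2:
        band = results.band(level=level, bin_width=bin_width)
        ax.fill_between(band["bin_center"], band["lower"], band["upper"],
                        color="0.8", zorder=0)
        ax.plot(band["bin_center"], band["mean"], color="k", lw=2)
    ax.set_yscale("log")
    ax.set_xlabel("distance from ingestion point (m)")
    ax.set_ylabel("probability of dispersal")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_cdf(results, ax=None, probs=(0.25, 0.50, 0.75, 0.95)):
    """Overall cumulative dispersal-distance curve with quantile rules."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    k = results.overall
    ax.step(k.support, np.cumsum(k.mass), where="post", color="k")
    styles = {0.50: "-", 0.25: "--", 0.75: "--", 0.95: ":"}
    for p in probs:
        ax.axvline(k.quantile(p), ls=styles.get(p, ":"), color="0.4", lw=1)
    ax.set_xlabel("distance from ingestion point (m)")
    ax.set_ylabel("cumulative probability of dispersal")
    ax.set_ylim(0, 1)
    return ax
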
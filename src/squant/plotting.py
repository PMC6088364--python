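"""Plot helpers: (B, M) plane, amplitude CDF fits, all-point histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_bm_plane", "plot_mixture_fit", "plot_all_point_histogram"]


def plot_bm_plane(bm, ax=None, by="event_class"):
    """Scatter cells in the burstiness/memory plane, colored by class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for key, sub in bm.groupby(by):
        ax.scatter(sub["b"], sub["m"], label=str(key), s=18, alpha=0.7)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("burstiness B")
    ax.set_ylabel("memory M")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_mixture_fit(fit2, fit1=None, ax=None):
    """Empirical amplitude CDF with the fitted cumulative-normal mixtures."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    model = fit2.model
    ax.step(model.x, model.y, where="post", color="0.4", lw=1, label="empirical CDF")
    xs = np.linspace(model.x[0], model.x[-1], 400)
    ax.plot(xs, fit2.cdf(xs), "k-", lw=1.5, label="2 components")
    if fit1 is not None:
        ax.plot(xs, fit1.cdf(xs), "k--", lw=1, label="1 component")
    ax.set_xlabel("amplitude (pA)")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_all_point_histogram(hist, fit=None, ax=None):
    """All-point histogram with the smoothed counts and baseline Gaussian."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    x = hist.centers
    ax.bar(x, hist.counts, width=1.0, color="0.85", label="counts")
    ax.plot(x, hist.smoothed_counts, "k-", lw=1, label="smoothed")
    if fit is not None:
        ax.plot(x, fit.gaussian(x), "r--", lw=1, label="baseline Gaussian")
    ax.set_xlabel("current (pA)")
    ax.set_ylabel("points per 1 pA bin")
    ax.legend(frameon=False, fontsize=8)
    return ax
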
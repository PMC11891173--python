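"""Diagnostic plots: per-sample paralog-age histograms with the fitted
Gaussian mixture, RF distance distributions, and gene-flow heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = [
    "plot_age_histogram",
    "plot_distance_distributions",
    "plot_matrix_heatmap",
]


def plot_age_histogram(ages, gmm_result=None, sample=None, ax=None, bins=40):
    """Histogram of duplication ages with the mixture density overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ages = np.asarray(list(ages), dtype=float)
    ax.hist(ages, bins=bins, density=True, alpha=0.6, color="#7aa6c2")
    if gmm_result is not None:
        xs = np.linspace(0, ages.max() * 1.05, 400)
        total = np.zeros_like(xs)
        for m, s, w in zip(gmm_result.means, gmm_result.sds, gmm_result.weights):
            comp = w * stats.norm.pdf(xs, m, s)
            total += comp
            ax.plot(xs, comp, "--", lw=1, color="#888888")
        ax.plot(xs, total, color="#c0392b", lw=2)
    ax.set_xlabel("paralog origin time (Mya)")
    ax.set_ylabel("density")
    if sample:
        ax.set_title(sample)
    return ax


def plot_distance_distributions(empirical, simulated, ax=None):
    """Side-by-side RF-distance histograms (empirical vs simulated)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    values = sorted(set(empirical.counts) | set(simulated.counts))
    width = 0.4
    xs = np.arange(len(values))
    emp = [empirical.counts.get(v, 0) / empirical.n for v in values]
    sim = [simulated.counts.get(v, 0) / simulated.n for v in values]
    ax.bar(xs - width / 2, emp, width, label=empirical.label, color="#2c6fa8")
    ax.bar(xs + width / 2, sim, width, label=simulated.label, color="#e67e22")
    ax.set_xticks(xs, [str(v) for v in values])
    ax.set_xlabel("RF distance to species tree")
    ax.set_ylabel("frequency")
    ax.legend()
    return ax


def plot_matrix_heatmap(matrix, ax=None, cmap="viridis", label="pi2"):
    """Heat map of a symmetric taxon-by-taxon matrix (pi2 or gamma)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    plt.colorbar(im, ax=ax, label=label)
    return ax
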
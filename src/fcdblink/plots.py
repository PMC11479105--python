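"""Basic plot artifacts: scatter, Bland–Altman, difference density."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = ["scatter_plot", "bland_altman_plot", "density_plot"]


def scatter_plot(x: Sequence[float], y: Sequence[float], path: str | Path,
                 label_x: str = "A", label_y: str = "B") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=6, alpha=0.4)
    lims = [min(np.min(x), np.min(y)), max(np.max(x), np.max(y))]
    ax.plot(lims, lims, "r--", lw=1)
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(x: Sequence[float], y: Sequence[float], path: str | Path,
                      title: str = "") -> None:
    """Conventional axes: x = pairwise mean, y = difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diff = x - y
    mean = (x + y) / 2
    bias = diff.mean()
    sd = diff.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=6, alpha=0.4)
    ax.axhline(bias, color="green", lw=1)
    for lim in (bias - 1.96 * sd, bias + 1.96 * sd):
        ax.axhline(lim, color="red", lw=1)
    ax.axhline(0, color="red", lw=0.8, ls=":")
    ax.set_xlabel("mean of paired values")
    ax.set_ylabel("difference (A - B)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_plot(diffs: Sequence[float], path: str | Path, title: str = "") -> None:
    """Gaussian KDE with Silverman's bandwidth; display only."""
    d = np.asarray(diffs, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if np.std(d) > 0:
        kde = stats.gaussian_kde(d, bw_method="silverman")
        grid = np.linspace(d.min(), d.max(), 400)
        ax.plot(grid, kde(grid))
    ax.axvline(0, color="red", lw=0.8, ls=":")
    ax.set_xlabel("difference (A - B)")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
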
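"""Publication-style figures: D* histogram with mixture overlay and
replicate bar plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mixture import MixtureFit, dstar_density
from .replicates import ReplicateSummary

__all__ = ["plot_dstar_histogram", "plot_immobile_bars"]


def plot_dstar_histogram(dstars, fit: MixtureFit | None = None, path=None, bins: int = 60):
    """Normalized D* histogram, optionally overlaid with the fitted mixture
    density and its components."""
    x = (
        dstars["d_star_um2_s"].to_numpy(dtype=float)
        if hasattr(dstars, "columns")
        else np.asarray(dstars, dtype=float)
    )
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(x, bins=bins, density=True, color="0.8", edgecolor="0.5", label="tracks")
    if fit is not None:
        grid = np.linspace(1e-4, max(x.max(), 3.0), 400)
        total = np.zeros_like(grid)
        for d, f in fit.species:
            comp = f * dstar_density(grid, d, fit.n_steps)
            total += comp
            ax.plot(grid, comp, "--", lw=1, label=f"D={d:.2f} ({100*f:.0f}%)")
        ax.plot(grid, total, "k-", lw=1.5, label="mixture")
    ax.set_xlabel(r"$D^*$ ($\mu$m$^2$/s)")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_immobile_bars(summaries: Sequence[ReplicateSummary], path=None):
    """Mean +/- SD immobile percentage per condition with replicate points."""
    fig, ax = plt.subplots(figsize=(3, 3.5))
    for i, s in enumerate(summaries):
        ax.bar(i, s.mean, yerr=s.sd, capsize=4, color="0.75", edgecolor="k")
        ax.plot(
            np.full(s.n_replicates, i) + np.linspace(-0.12, 0.12, s.n_replicates),
            s.replicate_fractions,
            "ko",
            ms=4,
        )
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([s.condition for s in summaries], rotation=20)
    ax.set_ylabel("immobile molecules (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
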
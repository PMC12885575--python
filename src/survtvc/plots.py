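"""Optional matplotlib rendering of survival curves and bias grids."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .curves import SurvivalCurve

__all__ = ["plot_curves", "plot_contour"]


def _axes(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=figsize)
    return fig, ax


def plot_curves(curve: SurvivalCurve, path: str | Path, figsize=(5, 4)) -> Path:
    """Step plot of one SurvivalCurve (all groups, CI bands where present)."""
    fig, ax = _axes(figsize)
    for label, g in curve.groups.items():
        ax.step(g.times, g.survival, where="post", label=label)
        if g.ci_low is not None and g.ci_high is not None:
            ax.fill_between(
                g.times, g.ci_low, g.ci_high, step="post", alpha=0.2, linewidth=0
            )
    if curve.t_change is not None:
        ax.axvline(curve.t_change, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel(f"time ({curve.origin_note})" if curve.origin_note else "time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(curve.method)
    ax.legend(title="group", frameon=False)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path


def plot_contour(grid, path: str | Path, figsize=(5, 4)) -> Path:
    """Filled contour of a bias grid (rows alpha_TVC, columns alpha_E)."""
    fig, ax = _axes(figsize)
    x = np.asarray(grid.columns, dtype=float)
    y = np.asarray(grid.index, dtype=float)
    cs = ax.contourf(x, y, grid.to_numpy(), levels=12, cmap="RdBu_r")
    fig.colorbar(cs, ax=ax, label="mean HR bias")
    ax.set_xlabel("alpha_E (event-time shape)")
    ax.set_ylabel("alpha_TVC (TVC-time shape)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return path
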
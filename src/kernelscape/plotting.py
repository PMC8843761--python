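"""Plot helpers for surfaces and partial-dependence curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["plot_surface", "plot_partial_dependence"]


def plot_surface(grid: RasterGrid, ax=None, title: str | None = None,
                 cmap: str = "viridis", **imshow_kwargs):
    """Render a raster surface with its projected extent on the axes."""
    if ax is None:
        _, ax = plt.subplots()
    xmin, ymin, xmax, ymax = grid.bounds
    im = ax.imshow(grid.values, extent=(xmin, xmax, ymin, ymax),
                   cmap=cmap, **imshow_kwargs)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    return ax


def plot_partial_dependence(curve: pd.DataFrame, variable: str, ax=None):
    """Ensemble partial-dependence curve with its 95% band across members."""
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve["value"], curve["lo"].clip(0, 1),
                    curve["hi"].clip(0, 1), color="0.8",
                    label="95% band across members")
    ax.plot(curve["value"], curve["mean"], color="crimson", label="mean")
    ax.set_xlabel(variable)
    ax.set_ylabel("predicted occurrence probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax
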
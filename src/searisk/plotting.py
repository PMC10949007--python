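"""Choropleth heat maps of one region's row of a pairwise matrix."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.patches import Polygon as MplPolygon

from .regions import RegionSet

#: low → high mapped yellow → blue, the ramp used for distance maps
YELLOW_BLUE = LinearSegmentedColormap.from_list(
    "yellow_blue", ["#ffe945", "#7ec4a0", "#2e6fb0", "#08306b"]
)
#: reversed ramp for risk maps: dark blue (low risk) → yellow (high risk)
BLUE_YELLOW = YELLOW_BLUE.reversed()

NO_DATA_COLOR = "#c8c8c8"
FOCUS_COLOR = "#ff8c00"


def _polygon_patches(geometry) -> list[MplPolygon]:
    geoms = getattr(geometry, "geoms", [geometry])
    return [MplPolygon(np.asarray(g.exterior.coords), closed=True) for g in geoms]


def ramp_position(value: float, vmin: float, vmax: float) -> float:
    """Normalized [0, 1] position of a value on the color ramp."""
    if vmax == vmin:
        return 0.0
    return float(np.clip((value - vmin) / (vmax - vmin), 0.0, 1.0))


def render_heatmap(
    matrix: pd.DataFrame,
    regions: RegionSet,
    focus_region_id: int,
    color_ramp=YELLOW_BLUE,
    title: str | None = None,
    path: str | Path | None = None,
):
    """Choropleth of the focus region's row of a pairwise matrix.

    Regions are filled by their value relative to the focus region on the
    given ramp (yellow→blue for distances; pass :data:`BLUE_YELLOW` for
    risks).  NA entries use a neutral no-data color and the focus region
    is drawn in a highlight color.  Returns the matplotlib figure.
    """
    if focus_region_id not in regions:
        raise ValueError(f"focus region {focus_region_id} not in region set")
    if regions[focus_region_id].geometry is None:
        raise ValueError(f"focus region {focus_region_id} has no geometry")
    row = matrix.loc[focus_region_id]
    finite = row[np.isfinite(row.values.astype(float))]
    vmin = float(finite.min()) if len(finite) else 0.0
    vmax = float(finite.max()) if len(finite) else 1.0
    norm = Normalize(vmin=vmin, vmax=vmax)

    fig, ax = plt.subplots(figsize=(8, 5))
    for region in regions:
        patches = _polygon_patches(region.geometry)
        if region.id == focus_region_id:
            color = FOCUS_COLOR
        else:
            val = float(row.get(region.id, np.nan))
            color = color_ramp(norm(val)) if np.isfinite(val) else NO_DATA_COLOR
        ax.add_collection(
            PatchCollection(patches, facecolor=color, edgecolor="black", linewidth=0.4)
        )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("longitude (°E)")
    ax.set_ylabel("latitude (°N)")
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=color_ramp)
    fig.colorbar(sm, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
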
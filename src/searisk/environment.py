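"""Regional sea-surface environment summaries and environmental distance.

Establishment risk is proxied by how similar two regions' coastal
environments are.  Each region is summarized by the annual mean of
sea-surface temperature (°C) and salinity (PSU) over the field grid cells
whose centers fall inside the region polygon, and pairwise environmental
distance is a configurable metric over those summaries.  Environmental
distances are comparative, not absolute, and carry no units.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy.spatial.distance import pdist, squareform

from .matrices import DistanceMatrix
from .regions import RegionSet

DEFAULT_VARIABLES = ("sst", "sss")


def _as_dataset(fields) -> xr.Dataset:
    if isinstance(fields, xr.Dataset):
        return fields
    if isinstance(fields, xr.DataArray):
        return fields.to_dataset(name=fields.name or "field")
    if isinstance(fields, Mapping):
        return xr.Dataset({k: v for k, v in fields.items()})
    raise TypeError("fields must be an xarray Dataset/DataArray or a mapping of them")


def summarize_region_env(
    fields,
    regions: RegionSet,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Per-region means of gridded environment fields.

    ``fields`` holds one or more variables on shared ``lat``/``lon``
    cell-center coordinates (WGS84 degrees).  The regional mean is taken
    over cells whose centers fall inside the region polygon, weighted by
    cos(latitude) to correct the varying area of lon/lat cells (set
    ``area_weighted=False`` for the plain mean).  Regions overlapping no
    finite cells get NaN; excluded regions are NaN throughout.
    """
    ds = _as_dataset(fields)
    if "lat" not in ds.coords or "lon" not in ds.coords:
        raise ValueError("fields must carry 'lat' and 'lon' coordinates")
    lon = np.asarray(ds["lon"].values, dtype=float)
    lat = np.asarray(ds["lat"].values, dtype=float)
    lon_grid, lat_grid = np.meshgrid(lon, lat)
    cell_w = np.cos(np.radians(lat_grid)) if area_weighted else np.ones_like(lat_grid)

    var_names = list(ds.data_vars)
    arrays = {}
    for name in var_names:
        da = ds[name].transpose("lat", "lon")
        vals = np.asarray(da.values, dtype=float)
        if not np.isfinite(vals).any():
            raise ValueError(f"field '{name}' contains no finite values")
        arrays[name] = vals

    out = pd.DataFrame(np.nan, index=regions.ids, columns=var_names, dtype=float)
    for region in regions:
        if region.excluded:
            continue
        geom = region.geometry
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, lon_grid, lat_grid)
        for name, vals in arrays.items():
            sel = inside & np.isfinite(vals)
            if not sel.any():
                continue  # stays NaN: zero overlapping cells
            w = cell_w[sel]
            out.loc[region.id, name] = float(np.sum(w * vals[sel]) / np.sum(w))
    return out


def env_distance(
    summaries: pd.DataFrame,
    metric: str = "standardized_euclidean",
    variable_weights: Mapping[str, float] | None = None,
) -> DistanceMatrix:
    """Pairwise environmental distance between regional summaries.

    Default metric: Euclidean distance after standardizing each variable
    to zero mean and unit variance across regions (population std), so
    temperature and salinity contribute on a common scale.  ``metric`` may
    also be ``"euclidean"`` (raw units); ``variable_weights`` scales each
    variable's contribution (applied as sqrt-weights on the columns).
    Regions with NaN summaries propagate NA rows/columns.
    """
    if summaries.shape[0] < 2:
        raise ValueError("need at least 2 regions to compute distances")
    x = summaries.astype(float)
    valid = x.notna().all(axis=1)
    if valid.sum() < 2:
        raise ValueError("need at least 2 regions with complete summaries")
    xv = x.loc[valid]
    if metric == "standardized_euclidean":
        std = xv.std(axis=0, ddof=0)
        zero = std[std == 0.0]
        if len(zero):
            raise ValueError(
                f"variables with zero variance across regions: {list(zero.index)}; "
                "use metric='euclidean' or drop them"
            )
        xv = (xv - xv.mean(axis=0)) / std
    elif metric != "euclidean":
        raise ValueError(f"unknown metric '{metric}'")
    if variable_weights is not None:
        w = np.array([float(variable_weights.get(c, 1.0)) for c in xv.columns])
        if np.any(w < 0):
            raise ValueError("variable weights must be nonnegative")
        xv = xv * np.sqrt(w)
    d = squareform(pdist(xv.values, metric="euclidean"))
    ids = list(summaries.index)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    vids = list(xv.index)
    mat.loc[vids, vids] = d
    return DistanceMatrix(mat, units="unitless", validate=False)
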
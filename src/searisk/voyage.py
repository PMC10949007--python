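"""Voyage metrics: least-cost over-water routes between region centroids.

The voyage-duration proxy is the shortest over-water distance (meters)
between region centroids on the transition graph; the voyage-path proxy is
the cross-latitudinal extent of that route in degrees.  For a route that
stays in one hemisphere the cross-latitude distance is max − min latitude;
for a route that crosses the equator the temperature gradient reverses
sign, so the distance used is the absolute latitude farthest from the
equator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .grid import OceanGrid, TransitionGraph, great_circle_m
from .matrices import DistanceMatrix
from .regions import Region, RegionSet

__all__ = [
    "PathSummary",
    "region_centroid",
    "centroid_cell",
    "all_pairs_distance",
    "unreachable_pairs",
    "extract_path",
    "lat_extent",
    "cross_latitude",
    "path_summaries",
]


@dataclass
class PathSummary:
    """Least-cost route summary for one ordered region pair."""

    origin_id: int
    dest_id: int
    least_cost_m: float
    node_sequence: np.ndarray  # graph node ids along the route
    min_lat: float
    max_lat: float
    cross_lat_deg: float


def region_centroid(region: Region, grid: OceanGrid) -> tuple[float, float]:
    """(lon, lat) endpoint for a region's voyages.

    The explicit override wins verbatim when set.  Otherwise the area
    centroid of the geometry is used; if the raster cell containing it is
    land, the point snaps to the center of the nearest water cell
    (great-circle nearest, ties broken by lowest (row, col)) — the
    automated equivalent of manually repositioning a land centroid to the
    nearest coastal location.
    """
    if region.centroid_override is not None:
        return region.centroid_override
    c = region.geometry.centroid
    lon, lat = float(c.x), float(c.y)
    cell = grid.spec.cell_of(lon, lat)
    if cell is not None and grid.is_water(*cell):
        return lon, lat
    row, col = nearest_water_cell(grid, lon, lat)
    return grid.spec.center(row, col)


def nearest_water_cell(grid: OceanGrid, lon: float, lat: float) -> tuple[int, int]:
    """Water cell whose center is great-circle nearest to a point.

    Ties are broken by lowest (row, col); water cells are scanned in
    row-major order so the first minimum wins.
    """
    rows, cols = np.nonzero(grid.water_mask)
    if rows.size == 0:
        raise ValueError("grid has no water cells")
    lons = grid.spec.lon_min + (cols + 0.5) * grid.spec.cell_size
    lats = grid.spec.lat_max - (rows + 0.5) * grid.spec.cell_size
    d = great_circle_m(lon, lat, lons, lats)
    # quantize to the micrometer so geometrically equal distances tie
    # exactly despite last-ulp float asymmetry, then let row-major
    # first-occurrence pick the lowest (row, col)
    k = int(np.argmin(np.round(d, 6)))
    return int(rows[k]), int(cols[k])


def centroid_cell(region: Region, grid: OceanGrid) -> tuple[int, int]:
    """Water cell used as the routing endpoint for a region."""
    lon, lat = region_centroid(region, grid)
    cell = grid.spec.cell_of(lon, lat)
    if cell is not None and grid.is_water(*cell):
        return cell
    return nearest_water_cell(grid, lon, lat)


def _region_nodes(graph: TransitionGraph, grid: OceanGrid, regions: RegionSet) -> dict[int, int]:
    return {
        r.id: graph.node_of(*centroid_cell(r, grid))
        for r in regions
        if not r.excluded
    }


def all_pairs_distance(
    graph: TransitionGraph, regions: RegionSet, grid: OceanGrid
) -> DistanceMatrix:
    """All-pairs shortest over-water distance between region centroids.

    Runs one single-source shortest-path sweep per origin region on the
    geo-corrected transition graph.  Excluded regions get NA rows and
    columns; unreachable pairs keep +inf and should be surfaced with
    :func:`unreachable_pairs` (a disconnected basin usually means a
    missing canal).
    """
    ids = regions.ids
    nodes = _region_nodes(graph, grid, regions)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    active = [i for i in ids if i in nodes]
    if active:
        src = np.array([nodes[i] for i in active])
        dist = dijkstra(graph.weights, directed=False, indices=src)
        dst_cols = src
        block = dist[:, dst_cols]
        # exact symmetry and zero diagonal, independent of sweep order
        block = np.minimum(block, block.T)
        np.fill_diagonal(block, 0.0)
        mat.loc[active, active] = block
    return DistanceMatrix(mat, units="meters", validate=False)


def unreachable_pairs(dm: DistanceMatrix) -> list[tuple[int, int]]:
    """Unordered region pairs whose centroids are not water-connected."""
    v = dm.df.values
    out = []
    ids = dm.labels
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isinf(v[i, j]):
                out.append((ids[i], ids[j]))
    return out


def _single_source(graph: TransitionGraph, src_node: int) -> np.ndarray:
    return dijkstra(graph.weights, directed=False, indices=src_node)


def _backtrack(graph: TransitionGraph, dist: np.ndarray, src: int, dst: int) -> np.ndarray:
    """Walk a shortest path backwards from dst, ties to the lowest node id."""
    if not np.isfinite(dist[dst]):
        raise ValueError(f"node {dst} is unreachable from node {src}")
    path = [dst]
    v = dst
    while v != src and dist[v] > 0:
        nbrs, w = graph.neighbors(v)
        ok = np.isclose(dist[nbrs] + w, dist[v], rtol=1e-9, atol=1e-6)
        # guard against zero-progress candidates from the tolerance
        ok &= dist[nbrs] < dist[v]
        if not ok.any():
            raise RuntimeError("path backtrack failed; inconsistent distances")
        v = int(nbrs[ok].min())
        path.append(v)
    path.reverse()
    return np.asarray(path, dtype=np.int64)


def extract_path(graph: TransitionGraph, src_node: int, dst_node: int) -> np.ndarray:
    """Node sequence of a shortest route from src to dst.

    The summed edge weights along the returned sequence equal the
    least-cost distance to within accumulation tolerance (≤1e-6 relative).
    Ties are broken deterministically toward the lowest node id, so
    path-derived outputs (latitude extents) are reproducible.
    """
    dist = _single_source(graph, src_node)
    return _backtrack(graph, dist, src_node, dst_node)


def lat_extent(path) -> tuple[float, float]:
    """(min_lat, max_lat) over the vertices of a route.

    ``path`` is either one sequence of (lon, lat) points or a list of such
    segments; for multiple segments the result takes the lowest minimum
    and highest maximum latitude across all of them.
    """
    arr = np.asarray(path, dtype=object)
    if arr.size == 0:
        raise ValueError("empty path has no latitude extent")
    try:
        pts = np.asarray(path, dtype=float)
    except (TypeError, ValueError):
        pts = np.concatenate([np.asarray(seg, dtype=float) for seg in path])
    if pts.ndim != 2 or pts.shape[1] != 2:
        if pts.ndim == 3:  # list of segments with equal lengths
            pts = pts.reshape(-1, 2)
        else:
            raise ValueError("path must be (lon, lat) points or segments thereof")
    if pts.shape[0] == 0:
        raise ValueError("empty path has no latitude extent")
    lats = pts[:, 1]
    return float(lats.min()), float(lats.max())


def cross_latitude(min_lat: float, max_lat: float) -> float:
    """Cross-latitude distance of a route, in degrees.

    Within one hemisphere this is max_lat − min_lat.  When the route
    strictly crosses the equator the en-route temperature gradient
    reverses sign, so the value used is the absolute latitude farthest
    from the equator.  A route that merely touches the equator (a bound of
    exactly 0) uses the single-hemisphere difference; both rules agree
    there.
    """
    if min_lat > max_lat:
        raise ValueError(f"min_lat {min_lat} > max_lat {max_lat}")
    for v in (min_lat, max_lat):
        if not -90.0 <= v <= 90.0:
            raise ValueError(f"latitude {v} outside [-90, 90]")
    if min_lat < 0.0 < max_lat:
        return max(abs(min_lat), abs(max_lat))
    return max_lat - min_lat


def path_summaries(
    graph: TransitionGraph, regions: RegionSet, grid: OceanGrid
) -> pd.DataFrame:
    """Per-pair route summaries: distance, latitude extent, cross-latitude.

    One row per unordered pair of non-excluded regions (origin listed
    first in region order).  Columns: origin_id, dest_id, least_cost_m,
    min_lat, max_lat, cross_lat_deg.  Unreachable pairs get NaN summaries
    apart from an infinite distance.
    """
    nodes = _region_nodes(graph, grid, regions)
    active = [i for i in regions.ids if i in nodes]
    rows = []
    for a_pos, i in enumerate(active):
        dist = _single_source(graph, nodes[i])
        for j in active[a_pos + 1 :]:
            if not np.isfinite(dist[nodes[j]]):
                rows.append(
                    {
                        "origin_id": i,
                        "dest_id": j,
                        "least_cost_m": np.inf,
                        "min_lat": np.nan,
                        "max_lat": np.nan,
                        "cross_lat_deg": np.nan,
                    }
                )
                continue
            seq = _backtrack(graph, dist, nodes[i], nodes[j])
            lats = graph.node_lat[seq]
            mn, mx = float(lats.min()), float(lats.max())
            rows.append(
                {
                    "origin_id": i,
                    "dest_id": j,
                    "least_cost_m": float(dist[nodes[j]]),
                    "min_lat": mn,
                    "max_lat": mx,
                    "cross_lat_deg": cross_latitude(mn, mx),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["origin_id", "dest_id", "least_cost_m", "min_lat", "max_lat", "cross_lat_deg"],
    )


def cross_latitude_matrix(summaries: pd.DataFrame, regions: RegionSet) -> DistanceMatrix:
    """Square cross-latitude distance matrix from path summaries (degrees)."""
    ids = regions.ids
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    active = regions.active_ids
    mat.loc[active, active] = 0.0 if active else np.nan
    for row in summaries.itertuples(index=False):
        mat.loc[row.origin_id, row.dest_id] = row.cross_lat_deg
        mat.loc[row.dest_id, row.origin_id] = row.cross_lat_deg
    for i in active:
        mat.loc[i, i] = 0.0
    return DistanceMatrix(mat, units="degrees", validate=False)
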
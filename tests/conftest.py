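"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own code paths: great-circle
distances come from the unit-vector/arccos formula (not the haversine the
package uses), graph adjacency is rebuilt by hand, shortest paths come
from networkx or exhaustive simple-path enumeration.
"""

from dataclasses import replace

import numpy as np
import pytest

from searisk import GridSpec, OceanGrid, ToyWorldSpec, build_transition, make_toy_world

R_EARTH = 6_371_000.0


def gc_oracle(lon1, lat1, lon2, lat2, radius=R_EARTH):
    """Great-circle distance via unit vectors and arccos (independent route)."""
    def unit(lon, lat):
        lam, phi = np.radians(lon), np.radians(lat)
        return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])

    dot = float(np.dot(unit(lon1, lat1), unit(lon2, lat2)))
    return radius * np.arccos(np.clip(dot, -1.0, 1.0))


def grid_from_mask(mask, lon_min=0.0, lat_max=None, cell=1.0, wrap=False):
    """OceanGrid from an explicit boolean mask (row 0 = northernmost)."""
    mask = np.asarray(mask, dtype=bool)
    nrows, ncols = mask.shape
    if lat_max is None:
        lat_max = nrows / 2.0  # center the grid on the equator
    spec = GridSpec(
        lon_min=lon_min,
        lon_max=lon_min + ncols * cell,
        lat_min=lat_max - nrows * cell,
        lat_max=lat_max,
        cell_size=cell,
        wrap_longitude=wrap,
    )
    return OceanGrid(spec, mask)


def oracle_edges(grid, wrap=None):
    """8-neighbor water-water cell pairs, rebuilt by explicit loops."""
    mask = grid.water_mask
    nrows, ncols = mask.shape
    if wrap is None:
        wrap = grid.spec.wrap_longitude
    pairs = set()
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c]:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2 = r + dr
                    c2 = c + dc
                    if not 0 <= r2 < nrows:
                        continue
                    if wrap:
                        c2 %= ncols
                    elif not 0 <= c2 < ncols:
                        continue
                    if mask[r2, c2] and (r, c) != (r2, c2):
                        pairs.add(frozenset([(r, c), (r2, c2)]))
    return {tuple(sorted(p)) for p in pairs}


def nx_graph(grid, wrap=None):
    """networkx graph over water cells with arccos-formula edge weights."""
    import networkx as nx

    g = nx.Graph()
    for (r1, c1), (r2, c2) in oracle_edges(grid, wrap=wrap):
        lon1, lat1 = grid.spec.center(r1, c1)
        lon2, lat2 = grid.spec.center(r2, c2)
        g.add_edge((r1, c1), (r2, c2), weight=gc_oracle(lon1, lat1, lon2, lat2))
    for r, c in zip(*np.nonzero(grid.water_mask)):
        g.add_node((int(r), int(c)))
    return g


def enumerate_shortest(graph, src, dst):
    """Minimum path length by exhaustive DFS over simple paths.

    Sums the package graph's own edge weights in path order, so the
    optimal path's float sum is bit-identical to what a label-setting
    sweep accumulates.  Only feasible on very small grids.
    """
    best = [np.inf]

    def dfs(v, total, visited):
        if total >= best[0]:
            return
        if v == dst:
            best[0] = total
            return
        nbrs, w = graph.neighbors(v)
        for u, wu in zip(nbrs, w):
            if u not in visited:
                visited.add(u)
                dfs(int(u), total + wu, visited)
                visited.remove(u)

    dfs(src, 0.0, {src})
    return best[0]


def label_correcting(graph, src):
    """Bellman-Ford-style label-correcting distances (independent sweep)."""
    n = graph.n_nodes
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    changed = True
    while changed:
        changed = False
        for v in range(n):
            if not np.isfinite(dist[v]):
                continue
            nbrs, w = graph.neighbors(v)
            relax = dist[v] + w
            better = relax < dist[nbrs]
            if better.any():
                dist[nbrs[better]] = relax[better]
                changed = True
    return dist


@pytest.fixture(scope="session")
def quiet_spec():
    """Toy-world spec with SST noise off (closed-form environment)."""
    return replace(ToyWorldSpec(), noise_sd=0.0)


@pytest.fixture(scope="session")
def toy_world():
    return make_toy_world(ToyWorldSpec())


@pytest.fixture(scope="session")
def quiet_world(quiet_spec):
    return make_toy_world(quiet_spec)


@pytest.fixture(scope="session")
def toy_graph(toy_world):
    return build_transition(toy_world.grid)
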
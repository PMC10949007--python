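"""Centroids, least-cost distances, path extraction and the cross-latitude rule."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from searisk import (
    Region,
    RegionSet,
    all_pairs_distance,
    build_transition,
    carve_channels,
    cross_latitude,
    extract_path,
    lat_extent,
    path_summaries,
    region_centroid,
    unreachable_pairs,
)
from searisk.voyage import nearest_water_cell

from conftest import enumerate_shortest, gc_oracle, grid_from_mask, label_correcting, nx_graph


def _regions_at_cells(grid, cells):
    """One tiny square region per water cell center."""
    regions = []
    for i, (r, c) in enumerate(cells, start=1):
        lon, lat = grid.spec.center(r, c)
        regions.append(
            Region(id=i, name=f"r{i}", geometry=shapely.box(lon - 0.2, lat - 0.2, lon + 0.2, lat + 0.2))
        )
    return RegionSet(regions)


class TestRegionCentroid:
    def test_square_over_water_gives_geometric_center(self):
        grid = grid_from_mask(np.ones((4, 4), bool))
        region = Region(id=1, name="r", geometry=shapely.box(1, -1, 3, 1))
        assert region_centroid(region, grid) == pytest.approx((2.0, 0.0))

    def test_override_returned_verbatim(self):
        grid = grid_from_mask(np.ones((4, 4), bool))
        region = Region(
            id=1, name="r", geometry=shapely.box(1, -1, 3, 1), centroid_override=(0.7, 1.9)
        )
        assert region_centroid(region, grid) == (0.7, 1.9)

    def test_land_centroid_snaps_to_nearest_water_cell(self):
        # 3x3 grid centered on the equator with a 1-cell island in the middle
        mask = np.ones((3, 3), bool)
        mask[1, 1] = False
        grid = grid_from_mask(mask)  # cell centers at lats 1, 0, -1
        region = Region(id=1, name="r", geometry=shapely.box(1, -0.5, 2, 0.5))
        lon, lat = region_centroid(region, grid)
        # oracle: exhaustive nearest-water search with independent distances,
        # rounded to the micrometer so exact ties resolve by (row, col)
        best = min(
            (
                (gc_oracle(1.5, 0.0, *grid.spec.center(r, c)), (r, c))
                for r in range(3)
                for c in range(3)
                if mask[r, c]
            ),
            key=lambda t: (round(t[0], 6), t[1]),
        )
        assert grid.spec.cell_of(lon, lat) == best[1]

    def test_tie_breaks_to_lowest_row_col(self):
        # point equidistant from the two water cells E and W of it
        mask = np.array([[True, False, True]])
        grid = grid_from_mask(mask, lat_max=0.5)  # single row on the equator
        r, c = nearest_water_cell(grid, 1.5, 0.0)
        assert (r, c) == (0, 0)

    def test_no_water_cells_errors(self):
        grid = grid_from_mask(np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="no water"):
            nearest_water_cell(grid, 0.5, 0.5)


class TestAllPairsDistance:
    def test_same_cell_distance_zero(self):
        grid = grid_from_mask(np.ones((3, 3), bool))
        graph = build_transition(grid)
        # two regions whose centroids share a cell
        regions = RegionSet(
            [
                Region(id=1, name="a", geometry=shapely.box(0.3, 0.8, 0.7, 1.2)),
                Region(id=2, name="b", geometry=shapely.box(0.4, 0.9, 0.6, 1.1)),
            ]
        )
        dm = all_pairs_distance(graph, regions, grid)
        assert dm.df.loc[1, 2] == 0.0

    def test_corner_to_corner_is_two_diagonal_hops(self):
        grid = grid_from_mask(np.ones((3, 3), bool))
        graph = build_transition(grid)
        regions = _regions_at_cells(grid, [(0, 0), (2, 2)])
        dm = all_pairs_distance(graph, regions, grid)
        n00, n11, n22 = (graph.node_of(i, i) for i in range(3))
        two_hops = graph.weights[n00, n11] + graph.weights[n11, n22]
        assert dm.df.loc[1, 2] == pytest.approx(two_hops, rel=1e-12)
        # exhaustive enumeration over simple paths agrees exactly
        assert dm.df.loc[1, 2] == enumerate_shortest(graph, n00, n22)

    def test_obstacle_increases_distance(self):
        open_grid = grid_from_mask(np.ones((3, 3), bool))
        blocked = np.ones((3, 3), bool)
        blocked[[0, 2], 1] = False  # keep only the middle of the center column
        blocked_grid = grid_from_mask(blocked)
        cells = [(0, 0), (2, 2)]
        d_open = all_pairs_distance(
            build_transition(open_grid), _regions_at_cells(open_grid, cells), open_grid
        ).df.loc[1, 2]
        d_blocked = all_pairs_distance(
            build_transition(blocked_grid), _regions_at_cells(blocked_grid, cells), blocked_grid
        ).df.loc[1, 2]
        assert d_blocked >= d_open
        wall = np.ones((3, 3), bool)
        wall[:2, 1] = False  # force a detour through the bottom row
        wall_grid = grid_from_mask(wall)
        d_wall = all_pairs_distance(
            build_transition(wall_grid), _regions_at_cells(wall_grid, cells), wall_grid
        ).df.loc[1, 2]
        assert d_wall > d_open

    def test_agrees_with_networkx_and_label_correcting(self):
        rng = np.random.default_rng(5)
        for trial in range(6):
            mask = rng.random((5, 6)) > 0.3
            mask[0, 0] = mask[4, 5] = True
            grid = grid_from_mask(mask, lat_max=20.0)
            graph = build_transition(grid)
            g_nx = nx_graph(grid)
            import networkx as nx

            cells = [(0, 0), (4, 5)]
            regions = _regions_at_cells(grid, cells)
            dm = all_pairs_distance(graph, regions, grid)
            src, dst = cells
            try:
                d_oracle = nx.dijkstra_path_length(g_nx, src, dst)
            except nx.NetworkXNoPath:
                assert np.isinf(dm.df.loc[1, 2])
                continue
            assert dm.df.loc[1, 2] == pytest.approx(d_oracle, rel=1e-9)
            d_lc = label_correcting(graph, graph.node_of(*src))
            assert dm.df.loc[1, 2] == pytest.approx(d_lc[graph.node_of(*dst)], rel=1e-12)

    def test_metric_properties_on_toy_world(self, toy_world, toy_graph):
        dm = all_pairs_distance(toy_graph, toy_world.regions, toy_world.grid)
        v = dm.df.values
        assert (v == v.T).all()
        assert (np.diag(v) == 0).all()
        n = v.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-6

    def test_excluded_region_gets_na_row_and_column(self, toy_world):
        from dataclasses import replace

        spec = replace(toy_world.spec, excluded_ids=(6,))
        from searisk import make_toy_world

        world = make_toy_world(spec)
        graph = build_transition(world.grid)
        dm = all_pairs_distance(graph, world.regions, world.grid)
        assert dm.df.loc[6].isna().all()
        assert dm.df[6].isna().all()
        assert dm.df.drop(index=6).drop(columns=6).notna().all().all()

    def test_disconnected_basins_reported(self):
        mask = np.ones((4, 5), bool)
        mask[:, 2] = False
        grid = grid_from_mask(mask)
        graph = build_transition(grid)
        regions = _regions_at_cells(grid, [(1, 0), (1, 4)])
        dm = all_pairs_distance(graph, regions, grid)
        assert unreachable_pairs(dm) == [(1, 2)]

    def test_carving_never_increases_distances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = rng.random((6, 8)) > 0.35
            mask[2, 1] = mask[3, 6] = True
            grid = grid_from_mask(mask)
            carved = carve_channels(grid, [[(1.5, 0.0), (6.5, 0.0)]])
            cells = [(2, 1), (3, 6)]
            d0 = all_pairs_distance(
                build_transition(grid), _regions_at_cells(grid, cells), grid
            ).df.loc[1, 2]
            d1 = all_pairs_distance(
                build_transition(carved), _regions_at_cells(carved, cells), carved
            ).df.loc[1, 2]
            assert d1 <= d0 or (np.isinf(d0) and np.isfinite(d1))


class TestExtractPath:
    def test_src_equals_dst_single_node(self):
        grid = grid_from_mask(np.ones((3, 3), bool))
        graph = build_transition(grid)
        n = graph.node_of(1, 1)
        assert extract_path(graph, n, n).tolist() == [n]

    def test_corner_path_is_two_diagonal_hops(self):
        grid = grid_from_mask(np.ones((3, 3), bool))
        graph = build_transition(grid)
        seq = extract_path(graph, graph.node_of(0, 0), graph.node_of(2, 2))
        cells = [(graph.node_row[n], graph.node_col[n]) for n in seq]
        assert cells == [(0, 0), (1, 1), (2, 2)]

    def test_path_sum_matches_least_cost(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 6)) > 0.25
        mask[0, 0] = mask[5, 5] = True
        grid = grid_from_mask(mask)
        graph = build_transition(grid)
        src, dst = graph.node_of(0, 0), graph.node_of(5, 5)
        from searisk.voyage import _single_source

        dist = _single_source(graph, src)
        if not np.isfinite(dist[dst]):
            pytest.skip("random mask disconnected; covered elsewhere")
        seq = extract_path(graph, src, dst)
        total = sum(graph.weights[a, b] for a, b in zip(seq, seq[1:]))
        assert total == pytest.approx(dist[dst], rel=1e-9)

    def test_reversal_has_same_length(self):
        grid = grid_from_mask(np.ones((4, 5), bool))
        graph = build_transition(grid)
        a, b = graph.node_of(0, 0), graph.node_of(3, 4)
        fwd = extract_path(graph, a, b)
        rev = extract_path(graph, b, a)
        w_fwd = sum(graph.weights[u, v] for u, v in zip(fwd, fwd[1:]))
        w_rev = sum(graph.weights[u, v] for u, v in zip(rev, rev[1:]))
        assert w_fwd == pytest.approx(w_rev, rel=1e-12)

    def test_unreachable_errors(self):
        mask = np.ones((3, 3), bool)
        mask[:, 1] = False
        grid = grid_from_mask(mask)
        graph = build_transition(grid)
        with pytest.raises(ValueError, match="unreachable"):
            extract_path(graph, graph.node_of(0, 0), graph.node_of(0, 2))

    def test_deterministic_under_ties(self):
        grid = grid_from_mask(np.ones((4, 4), bool))
        graph = build_transition(grid)
        a, b = graph.node_of(0, 0), graph.node_of(0, 3)
        seqs = [extract_path(graph, a, b).tolist() for _ in range(3)]
        assert seqs[0] == seqs[1] == seqs[2]


class TestLatExtent:
    def test_single_row_path(self):
        pts = [(0.5, 2.5), (1.5, 2.5), (2.5, 2.5)]
        assert lat_extent(pts) == (2.5, 2.5)

    def test_multiple_segments_take_outer_bounds(self):
        seg1 = [(0, 0), (5, 10)]
        seg2 = [(1, -5), (2, 3)]
        assert lat_extent([seg1, seg2]) == (-5.0, 10.0)

    def test_reversal_invariance(self):
        pts = [(0, 1), (1, 7), (2, -3)]
        assert lat_extent(pts) == lat_extent(pts[::-1])

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            lat_extent([])


class TestCrossLatitude:
    @pytest.mark.parametrize(
        "mn, mx, expected",
        [
            (10, 40, 30),       # single hemisphere: plain difference
            (-10, 40, 40),      # equator crossing: farthest |latitude|
            (-40, 10, 40),
            (5, 5, 0),
            (0, 25, 25),        # equator touch: both rules agree
            (-25, 0, 25),
            (-84.92, 3.0, 84.92),
        ],
    )
    def test_rule(self, mn, mx, expected):
        assert cross_latitude(mn, mx) == pytest.approx(expected)

    def test_inverted_bounds_error(self):
        with pytest.raises(ValueError):
            cross_latitude(10, -10)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            cross_latitude(-95, 10)

    @given(
        mn=st.floats(-90, 90, allow_nan=False),
        mx=st.floats(-90, 90, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounded_by_plain_difference(self, mn, mx):
        if mn > mx:
            mn, mx = mx, mn
        c = cross_latitude(mn, mx)
        assert 0 <= c <= mx - mn + 1e-12
        strictly_crossing = mn < 0 < mx
        if not strictly_crossing:
            assert c == mx - mn
        else:
            assert c == max(abs(mn), abs(mx))
            # equality with the plain difference only if one bound is ~0
            if c < mx - mn:
                assert mn < 0 < mx


class TestPathSummaries:
    def test_summaries_consistent_with_distances(self, toy_world, toy_graph):
        dm = all_pairs_distance(toy_graph, toy_world.regions, toy_world.grid)
        ps = path_summaries(toy_graph, toy_world.regions, toy_world.grid)
        for row in ps.itertuples(index=False):
            assert row.least_cost_m == pytest.approx(
                dm.df.loc[row.origin_id, row.dest_id], rel=1e-9
            )
            assert row.min_lat <= row.max_lat
            assert row.cross_lat_deg == cross_latitude(row.min_lat, row.max_lat)

    def test_cross_hemisphere_pairs_use_equator_rule(self, toy_world, toy_graph):
        ps = path_summaries(toy_graph, toy_world.regions, toy_world.grid)
        row = ps[(ps.origin_id == 1) & (ps.dest_id == 3)].iloc[0]
        assert row.min_lat < 0 < row.max_lat
        assert row.cross_lat_deg == max(abs(row.min_lat), abs(row.max_lat))
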
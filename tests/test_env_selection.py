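"""Convex hulls, buffered calibration regions and collinearity pruning."""

import numpy as np
import pytest
import shapely

from bftb_sdm.env_selection import (
    _distance_km_to_geometry,
    build_calibration_region,
    build_mcp,
    select_variables,
)
from bftb_sdm.occurrences import OccurrenceSet
from bftb_sdm.raster import Grid, RasterGrid
from bftb_sdm.synthetic import simulate_landscape, simulate_species, NicheSpec


def brute_force_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n^3) hull-vertex oracle: a point is a vertex iff it is not inside
    (or on) a triangle/segment of the others for some strict side test."""
    hull = shapely.MultiPoint([tuple(p) for p in points]).convex_hull
    # oracle via extreme-point definition: p is on the hull iff there is a
    # half-plane through p containing all points
    verts = set()
    pts = [tuple(p) for p in points]
    for p in pts:
        others = [q for q in pts if q != p]
        found = False
        for q in pts:
            for r in pts:
                ax, ay = q[0] - p[0], q[1] - p[1]
                bx, by = r[0] - p[0], r[1] - p[1]
                nx, ny = -(ay + by), (ax + bx)
                if all((o[0] - p[0]) * nx + (o[1] - p[1]) * ny <= 1e-12 for o in others):
                    found = True
                    break
            if found:
                break
        if found:
            verts.add(p)
    return verts


class TestMcp:
    def test_triangle(self):
        pts = np.array([[0, 0], [2, 0], [1, 2]])
        hull = build_mcp(pts)
        assert hull.geom_type == "Polygon"
        assert set(map(tuple, np.asarray(hull.exterior.coords)[:-1])) == set(
            map(tuple, pts)
        )

    def test_two_points_give_segment(self):
        hull = build_mcp(np.array([[0, 0], [1, 1]]))
        assert hull.geom_type == "LineString"

    def test_one_point_gives_point(self):
        assert build_mcp(np.array([[3, 4]])).geom_type == "Point"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_mcp(np.empty((0, 2)))

    def test_matches_extreme_point_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (40, 2))
        hull = build_mcp(pts)
        got = set(map(tuple, np.asarray(hull.exterior.coords)[:-1]))
        # every hull vertex is an input point; interior points are excluded
        assert got <= set(map(tuple, pts))
        inside = [p for p in map(tuple, pts) if p not in got]
        for p in inside:
            assert hull.covers(shapely.Point(p))
        # hull of the vertices alone reproduces the hull
        assert build_mcp(np.array(sorted(got))).equals(hull)


class TestCalibrationRegion:
    def test_single_occurrence_radius(self, flat_grid):
        grid, land = flat_grid
        occ = OccurrenceSet(species="x", points=[[102.5, 22.5]])
        region = build_calibration_region(occ, land, threshold_km=100.0)
        # brute force: per-cell haversine-ish distance to the point
        from bftb_sdm.occurrences import haversine_km

        lon2d, lat2d = grid.center_arrays()
        expect = np.zeros(grid.shape, bool)
        for i in range(grid.nrows):
            for j in range(grid.ncols):
                expect[i, j] = (
                    haversine_km((lon2d[i, j], lat2d[i, j]), (102.5, 22.5)) <= 100.0
                )
        got = region.region_mask.values > 0
        # local-plane vs haversine may disagree only within ~1% of the radius
        disputed = got != expect
        if disputed.any():
            for i, j in np.argwhere(disputed):
                d = haversine_km((lon2d[i, j], lat2d[i, j]), (102.5, 22.5))
                assert abs(d - 100.0) < 2.0

    def test_zero_threshold_keeps_hull_cells_only(self, flat_grid):
        grid, land = flat_grid
        pts = np.array([[101.0, 21.0], [104.0, 21.0], [104.0, 24.0], [101.0, 24.0]])
        occ = OccurrenceSet(species="x", points=pts)
        region = build_calibration_region(occ, land, threshold_km=0.0)
        hull = build_mcp(pts)
        lon2d, lat2d = grid.center_arrays()
        expect = shapely.contains_xy(hull, lon2d.ravel(), lat2d.ravel()).reshape(grid.shape)
        assert np.array_equal(region.region_mask.values > 0, expect)

    def test_cell_count_matches_per_cell_brute_force(self, flat_grid):
        grid, land = flat_grid
        pts = np.array([[101.2, 21.3], [103.7, 22.1], [102.4, 24.2]])
        occ = OccurrenceSet(species="x", points=pts)
        region = build_calibration_region(occ, land, threshold_km=150.0)
        hull = build_mcp(pts)
        lon2d, lat2d = grid.center_arrays()
        dist = _distance_km_to_geometry(lon2d.ravel(), lat2d.ravel(), hull)
        expect = (dist <= 150.0).reshape(grid.shape)
        assert int(np.nansum(region.region_mask.values)) == int(expect.sum())

    def test_every_occurrence_cell_inside_region(self, small_landscape):
        sp = simulate_species(small_landscape, NicheSpec(), 12, seed=3, name="x")
        region = build_calibration_region(sp.occurrences, small_landscape.land_mask, 400.0)
        g = small_landscape.grid
        for lon, lat in sp.occurrences.coords:
            r, c = g.cell_of(lon, lat)
            assert region.region_mask.values[r, c] == 1.0

    def test_region_monotone_in_threshold(self, flat_grid):
        grid, land = flat_grid
        occ = OccurrenceSet(species="x", points=[[101.0, 21.0], [103.0, 23.0]])
        small = build_calibration_region(occ, land, threshold_km=50.0)
        big = build_calibration_region(occ, land, threshold_km=200.0)
        s = small.region_mask.values > 0
        b = big.region_mask.values > 0
        assert np.all(b[s])


class TestSelectVariables:
    def test_perfectly_correlated_pair_keeps_higher_auc(self):
        ls = simulate_landscape(
            extent=(100, 18, 105, 23), resolution_arcmin=15, n_extra_layers=2,
            seed=3, correlate=("tmin_cold", "env14", 1.0),
        )
        sp = simulate_species(ls, NicheSpec(layers=("tmin_cold",), betas=(6.0,)), 25, seed=4)
        region = build_calibration_region(sp.occurrences, ls.land_mask, 400.0)
        sel = select_variables(
            ls.layers, sp.occurrences, region,
            candidate_names=("tmin_cold", "env14"), seed=0,
        )
        assert len(sel.retained_names) == 1
        kept = sel.retained_names[0]
        dropped = ({"tmin_cold", "env14"} - {kept}).pop()
        assert sel.jackknife_auc[kept] >= sel.jackknife_auc[dropped]

    def test_uncorrelated_layers_all_retained(self, small_landscape):
        sp = simulate_species(small_landscape, NicheSpec(), 15, seed=5)
        region = build_calibration_region(sp.occurrences, small_landscape.land_mask, 400.0)
        names = ("tmin_cold", "pop_density", "elev_range")
        vals = np.column_stack(
            [small_landscape.layers[n].values[small_landscape.land] for n in names]
        )
        corr = np.corrcoef(vals, rowvar=False)
        assume_ok = np.abs(corr[np.triu_indices(3, 1)]).max() < 0.8
        sel = select_variables(small_landscape.layers, sp.occurrences, region, names)
        if assume_ok:
            assert set(sel.retained_names) == set(names)

    def test_planted_duplicate_dropped_independent_kept(self):
        """B is a noisy copy of the niche-driving layer A; C is independent:
        pruning keeps {A, C}."""
        ls = simulate_landscape(
            extent=(100, 18, 106, 24), resolution_arcmin=15, n_extra_layers=2,
            seed=9, correlate=("tmin_cold", "env14", 0.97),
        )
        sp = simulate_species(
            ls, NicheSpec(layers=("tmin_cold",), betas=(7.0,), prevalence=0.15),
            30, seed=10,
        )
        region = build_calibration_region(sp.occurrences, ls.land_mask, 400.0)
        sel = select_variables(
            ls.layers, sp.occurrences, region,
            candidate_names=("tmin_cold", "env14", "pop_density"), seed=0,
        )
        assert set(sel.retained_names) == {"tmin_cold", "pop_density"}

    def test_retained_pairs_below_threshold(self, small_landscape):
        sp = simulate_species(small_landscape, NicheSpec(), 20, seed=6)
        region = build_calibration_region(sp.occurrences, small_landscape.land_mask, 400.0)
        names = tuple(small_landscape.layers)[:8]
        sel = select_variables(small_landscape.layers, sp.occurrences, region, names)
        kept = list(sel.retained_names)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert abs(sel.pearson.loc[a, b]) < 0.8

    def test_single_candidate_passthrough(self, small_landscape):
        sp = simulate_species(small_landscape, NicheSpec(), 10, seed=7)
        region = build_calibration_region(sp.occurrences, small_landscape.land_mask, 400.0)
        sel = select_variables(
            small_landscape.layers, sp.occurrences, region, candidate_names=("tano",)
        )
        assert sel.retained_names == ("tano",)
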
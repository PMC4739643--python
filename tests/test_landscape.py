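"""Derived landscape layers against brute-force oracles on small grids."""

import numpy as np
import pytest

from energyscape.geometry import GridGeometry, read_ascii_grid, write_ascii_grid
from energyscape.landscape import (
    LandscapeStack,
    distance_to_forest_edge,
    distance_to_roads,
    focal_heterogeneity,
    focal_proportion_urban,
    pct_urban_in_homerange,
)

CLASSES = ["developed_high", "deciduous_forest", "grassland", "wetland"]
CELL = 30.0


def make_stack(land, roads=None):
    n = land.shape[0]
    geom = GridGeometry(0.0, 0.0, CELL, land.shape[1], n)
    roads = np.zeros(land.shape, dtype=bool) if roads is None else roads
    return LandscapeStack(geometry=geom, land_cover=land, class_names=CLASSES, roads=roads)


@pytest.fixture()
def random_stack(rng):
    land = rng.integers(0, 4, (16, 16))
    land[0, 0] = 1  # ensure forest and non-forest both present
    land[0, 1] = 0
    roads = rng.uniform(size=(16, 16)) < 0.1
    roads[3, 3] = True
    return make_stack(land, roads)


def _brute_distance(mask_src, cell):
    """O(n^2) nearest source-cell-center distance."""
    n0, n1 = mask_src.shape
    src = np.argwhere(mask_src)
    out = np.full(mask_src.shape, np.inf)
    for i in range(n0):
        for j in range(n1):
            d = np.hypot(src[:, 0] - i, src[:, 1] - j).min()
            out[i, j] = d * cell
    return out


class TestDistanceToForestEdge:
    def test_matches_brute_force(self, random_stack):
        got = distance_to_forest_edge(random_stack)
        forest = random_stack.forest_mask
        expect = np.where(
            forest,
            _brute_distance(~forest, CELL),
            _brute_distance(forest, CELL),
        )
        np.testing.assert_allclose(got, expect)

    def test_half_plane_closed_form(self):
        land = np.zeros((8, 8), dtype=int)
        land[:, 4:] = 1  # columns 4.. are forest
        stack = make_stack(land)
        got = distance_to_forest_edge(stack)
        # non-forest column j is (4 - j) cells from the nearest forest center
        for j in range(4):
            np.testing.assert_allclose(got[:, j], (4 - j) * CELL)
        for j in range(4, 8):
            np.testing.assert_allclose(got[:, j], (j - 3) * CELL)

    def test_edge_adjacent_within_cell(self, random_stack):
        got = distance_to_forest_edge(random_stack)
        forest = random_stack.forest_mask
        # any forest cell orthogonally adjacent to non-forest is one cell away
        adj = forest[:, :-1] & ~forest[:, 1:]
        assert (got[:, :-1][adj] <= CELL).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            distance_to_forest_edge(make_stack(np.ones((8, 8), dtype=int)))

    def test_lipschitz(self, random_stack):
        d = distance_to_forest_edge(random_stack)
        assert np.all(np.abs(np.diff(d, axis=0)) <= CELL + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= CELL + 1e-9)


class TestFocalProportionUrban:
    def test_uniform_maps(self):
        urb = make_stack(np.zeros((16, 16), dtype=int))  # all developed_high
        np.testing.assert_allclose(focal_proportion_urban(urb, 100.0), 1.0)
        nat = make_stack(np.ones((16, 16), dtype=int))
        np.testing.assert_allclose(focal_proportion_urban(nat, 100.0), 0.0)

    def test_matches_brute_force(self, random_stack):
        radius = 75.0
        got = focal_proportion_urban(random_stack, radius)
        urban = random_stack.urban_mask
        n = 16
        for i in range(n):
            for j in range(n):
                cnt = tot = 0
                for a in range(n):
                    for b in range(n):
                        if (a - i) ** 2 + (b - j) ** 2 <= (radius / CELL) ** 2:
                            tot += 1
                            cnt += urban[a, b]
                assert got[i, j] == pytest.approx(cnt / tot)

    def test_small_radius_rejected(self, random_stack):
        with pytest.raises(ValueError):
            focal_proportion_urban(random_stack, radius=10.0)


class TestFocalHeterogeneity:
    def test_uniform_disc_zero(self):
        stack = make_stack(np.full((16, 16), 2, dtype=int))
        np.testing.assert_allclose(focal_heterogeneity(stack, 100.0), 0.0, atol=1e-12)

    def test_two_class_half_split(self):
        # vertical stripes alternating two classes: every disc is ~50/50
        land = np.tile(np.arange(16) % 2, (16, 1))
        got = focal_heterogeneity(make_stack(land), radius=200.0)
        assert got[8, 8] == pytest.approx(np.log(2), rel=0.05)

    def test_matches_brute_force(self, random_stack):
        radius = 75.0
        got = focal_heterogeneity(random_stack, radius)
        n = 16
        for i in range(0, n, 3):
            for j in range(0, n, 3):
                counts = np.zeros(len(CLASSES))
                for a in range(n):
                    for b in range(n):
                        if (a - i) ** 2 + (b - j) ** 2 <= (radius / CELL) ** 2:
                            counts[random_stack.land_cover[a, b]] += 1
                p = counts[counts > 0] / counts.sum()
                assert got[i, j] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)


class TestDistanceToRoads:
    def test_road_cell_zero_and_brute_force(self, random_stack):
        got = distance_to_roads(random_stack)
        assert (got[random_stack.roads] == 0).all()
        np.testing.assert_allclose(got, _brute_distance(random_stack.roads, CELL))

    def test_no_roads_rejected(self):
        with pytest.raises(ValueError):
            distance_to_roads(make_stack(np.zeros((8, 8), dtype=int)))


class TestPctUrbanInHomerange:
    def test_extremes_and_checkerboard(self):
        land = np.indices((16, 16)).sum(axis=0) % 2  # 0=developed, 1=forest
        stack = make_stack(land)
        assert pct_urban_in_homerange(stack, np.ones((16, 16), bool)) == 0.5
        assert pct_urban_in_homerange(stack, land == 0) == 1.0
        one = np.zeros((16, 16), bool)
        one[0, 1] = True  # a single forest cell
        assert pct_urban_in_homerange(stack, one) == 0.0

    def test_empty_mask_rejected(self, random_stack):
        with pytest.raises(ValueError):
            pct_urban_in_homerange(random_stack, np.zeros((16, 16), bool))


def test_ascii_grid_roundtrip(tmp_path, rng):
    geom = GridGeometry(10.0, -5.0, 30.0, 7, 5)
    grid = rng.normal(size=(5, 7))
    grid[0, 0] = np.nan
    write_ascii_grid(tmp_path / "g.asc", grid, geom)
    back, geom2 = read_ascii_grid(tmp_path / "g.asc")
    assert geom2 == geom
    np.testing.assert_allclose(back[~np.isnan(grid)], grid[~np.isnan(grid)], rtol=1e-9)
    assert np.isnan(back[0, 0])
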
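import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull, Voronoi

from voroclust import (
    Box,
    LocalizationSet,
    build_delaunay,
    build_voronoi,
    cell_polytope,
    construct_cell,
    direct_neighbors,
    flag_border_cells,
    simulate_uniform,
)
from voroclust.errors import EmptyInputError, GeometryError


def _circumsphere(pts):
    """Center and radius of the sphere through dim+1 points."""
    p0 = pts[0]
    a = 2.0 * (pts[1:] - p0)
    b = np.sum(pts[1:] ** 2 - p0**2, axis=1)
    c = np.linalg.solve(a, b)
    return c, np.linalg.norm(pts[0] - c)


def _brute_force_delaunay_adjacency(coords):
    """All empty-circumsphere simplices by exhaustive enumeration."""
    n, dim = coords.shape
    adj = {i: set() for i in range(n)}
    for simplex in itertools.combinations(range(n), dim + 1):
        pts = coords[list(simplex)]
        if abs(np.linalg.det(pts[1:] - pts[0])) < 1e-12:
            continue
        c, r = _circumsphere(pts)
        others = np.setdiff1d(np.arange(n), simplex)
        if np.all(np.linalg.norm(coords[others] - c, axis=1) > r * (1 - 1e-12)):
            for a in simplex:
                for b in simplex:
                    if a != b:
                        adj[a].add(b)
    return adj


class TestDelaunay:
    def test_single_tetrahedron(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        dt = build_delaunay(LocalizationSet(coords))
        assert len(dt.simplices) == 1
        for i in range(4):
            assert set(direct_neighbors(dt, i)) == set(range(4)) - {i}

    def test_tetrahedron_plus_centroid_matches_brute_force(self):
        coords = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0.25, 0.25, 0.25]]
        )
        dt = build_delaunay(LocalizationSet(coords))
        oracle = _brute_force_delaunay_adjacency(coords)
        assert set(direct_neighbors(dt, 4)) == {0, 1, 2, 3}
        for i in range(5):
            assert set(direct_neighbors(dt, i)) == oracle[i]

    def test_empty_circumsphere_property_random(self):
        locs = simulate_uniform(150, Box([0, 0, 0], [1.0, 1, 1]), seed=11)
        dt = build_delaunay(locs)
        for simplex in dt.simplices:
            c, r = _circumsphere(dt.coords[simplex])
            others = np.setdiff1d(np.arange(locs.n), simplex)
            d = np.linalg.norm(dt.coords[others] - c, axis=1)
            assert np.all(d > r * (1 - 1e-9))

    def test_grid_center_has_face_neighbors(self, grid_3x3x3):
        dt = build_delaunay(LocalizationSet(grid_3x3x3))
        center = 13
        ring = set(direct_neighbors(dt, center))
        face_adjacent = {4, 10, 12, 14, 16, 22}
        assert face_adjacent <= ring

    def test_one_ring_symmetry_and_irreflexivity(self, uniform_300):
        dt = build_delaunay(uniform_300)
        for i in range(0, dt.n_points, 17):
            ring = direct_neighbors(dt, i)
            assert i not in ring
            for j in ring:
                assert i in direct_neighbors(dt, int(j))

    def test_index_error(self, uniform_300):
        dt = build_delaunay(uniform_300)
        with pytest.raises(IndexError):
            direct_neighbors(dt, 300)

    def test_degenerate_inputs(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError, match="collinear|coplanar"):
            build_delaunay(LocalizationSet(line))
        plane = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(GeometryError, match="coplanar"):
            build_delaunay(LocalizationSet(plane))
        with pytest.raises(EmptyInputError):
            build_delaunay(LocalizationSet(np.array([[0.0, 0, 0], [1, 1, 1]])))

    def test_duplicates_merged_keeping_first(self):
        base = simulate_uniform(50, Box([0, 0, 0], [1.0, 1, 1]), seed=2).coords
        coords = np.vstack([base, base[:10]])
        dt = build_delaunay(LocalizationSet(coords))
        assert dt.n_points == 50
        assert np.array_equal(dt.inverse[50:], dt.inverse[:10])
        assert np.array_equal(dt.unique_index, np.arange(50))


class TestConstructCell:
    def test_two_point_half_space(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        box = Box([-1, -1, -1], [3, 1, 1])
        cell = construct_cell(coords, 0, [1], box, with_polytope=True)
        assert cell.size == pytest.approx(8.0, rel=1e-12)
        assert cell.is_border
        assert list(cell.neighbors) == [1]
        assert len(cell.polytope.vertices) == 8
        assert len(cell.polytope.faces) == 6

    def test_grid_interior_cell_is_unit_cube(self, grid_3x3x3):
        box = Box([-2, -2, -2], [4, 4, 4])
        dt = build_delaunay(LocalizationSet(grid_3x3x3, bounds=box))
        cell = construct_cell(dt.coords, 13, dt.one_ring(13), box,
                              with_polytope=True)
        assert cell.size == pytest.approx(1.0, rel=1e-12)
        assert not cell.is_border
        assert cell.polytope.measure == pytest.approx(1.0, rel=1e-12)

    def test_coincident_neighbor_raises(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [1, 1, 1]])
        with pytest.raises(GeometryError):
            construct_cell(coords, 0, [1, 2], Box([-2] * 3, [2] * 3))

    def test_one_ring_equals_all_pairs_oracle(self):
        """Duality: one-ring bisectors give the same cell as all bisectors."""
        locs = simulate_uniform(200, Box([0, 0, 0], [1000.0] * 3), seed=9)
        vd = build_voronoi(locs, clip_bounds=locs.bounds)
        everyone = np.arange(locs.n)
        for i in range(locs.n):
            oracle = construct_cell(
                locs.coords, i, np.delete(everyone, i), locs.bounds
            )
            assert vd.sizes[i] == pytest.approx(oracle.size, rel=1e-9)
            assert bool(vd.is_border[i]) == oracle.is_border


class TestVoronoiDiagram:
    def test_two_point_mirror_cells(self):
        locs = LocalizationSet(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            bounds=Box([-1, -1, -1], [3, 1, 1]),
        )
        vd = build_voronoi(locs, clip_bounds=locs.bounds)
        assert vd.sizes == pytest.approx([8.0, 8.0], rel=1e-12)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_partition_of_space(self, dim):
        box = Box(np.zeros(dim), np.full(dim, 1000.0))
        locs = simulate_uniform(1000, box, seed=dim)
        vd = build_voronoi(locs, clip_bounds=box)
        assert vd.sizes.sum() == pytest.approx(box.measure, rel=1e-6)

    def test_fast_and_reference_engines_agree(self, uniform_300):
        vd_f = build_voronoi(uniform_300, engine="fast")
        vd_r = build_voronoi(uniform_300, engine="reference")
        np.testing.assert_allclose(vd_f.sizes, vd_r.sizes, rtol=1e-9)
        assert np.array_equal(vd_f.is_border, vd_r.is_border)

    def test_agrees_with_scipy_voronoi_regions_2d(self):
        """Independent oracle: interior region areas from scipy's global
        Voronoi construction (shoelace over each closed region)."""
        locs = simulate_uniform(250, Box([0, 0], [1000.0, 1000.0]), seed=3)
        vd = flag_border_cells(build_voronoi(locs), locs.bounds)
        sv = Voronoi(locs.coords)
        for i in np.flatnonzero(~vd.is_border):
            region = sv.regions[sv.point_region[i]]
            assert -1 not in region
            poly = sv.vertices[region]
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(np.roll(x, 1), y))
            assert vd.sizes[i] == pytest.approx(area, rel=1e-9)

    def test_translation_invariance(self, uniform_300):
        vd = build_voronoi(uniform_300, clip_bounds=uniform_300.bounds)
        shift = np.array([123.0, -45.0, 678.0])
        moved = LocalizationSet(
            uniform_300.coords + shift,
            bounds=Box(uniform_300.bounds.lo + shift, uniform_300.bounds.hi + shift),
        )
        vd2 = build_voronoi(moved, clip_bounds=moved.bounds)
        np.testing.assert_allclose(vd.sizes, vd2.sizes, rtol=1e-6)

    def test_rotation_invariance_of_interior_cells(self, uniform_300):
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        center = uniform_300.coords.mean(axis=0)
        big = Box(center - 3000.0, center + 3000.0)
        vd = flag_border_cells(
            build_voronoi(uniform_300.with_bounds(big), clip_bounds=big),
            uniform_300.bounds,
        )
        rot = (uniform_300.coords - center) @ q.T + center
        rlocs = LocalizationSet(rot, bounds=big)
        vdr = build_voronoi(rlocs, clip_bounds=big)
        keep = ~vd.is_border
        np.testing.assert_allclose(vd.sizes[keep], vdr.sizes[keep], rtol=1e-6)

    def test_row_permutation_invariance(self, uniform_300):
        vd = build_voronoi(uniform_300, clip_bounds=uniform_300.bounds)
        rng = np.random.default_rng(0)
        perm = rng.permutation(uniform_300.n)
        permuted = LocalizationSet(
            uniform_300.coords[perm], bounds=uniform_300.bounds
        )
        vd2 = build_voronoi(permuted, clip_bounds=uniform_300.bounds)
        np.testing.assert_allclose(vd2.sizes, vd.sizes[perm], rtol=1e-9)
        assert np.array_equal(vd2.is_border, vd.is_border[perm])

    def test_border_flags_match_vertex_containment_oracle(self, uniform_300):
        bounds = uniform_300.bounds
        vd = flag_border_cells(build_voronoi(uniform_300), bounds)
        tol = 1e-9 * bounds.diagonal
        for i in range(0, uniform_300.n, 7):
            poly = cell_polytope(vd, i)
            outside = bool(
                np.any(poly.vertices <= bounds.lo + tol)
                or np.any(poly.vertices >= bounds.hi - tol)
            )
            assert bool(vd.is_border[i]) == outside

    def test_grid_corner_cells_flagged(self):
        axes = np.arange(2.0)
        pts = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
        locs = LocalizationSet(pts)
        vd = flag_border_cells(build_voronoi(locs), locs.bounds)
        assert np.all(vd.is_border)  # every point of a 2x2x2 grid is on the hull

    def test_polytope_volume_matches_clipped_size(self, uniform_300):
        vd = build_voronoi(uniform_300, clip_bounds=uniform_300.bounds)
        for i in (0, 50, 123, 299):
            poly = cell_polytope(vd, i)
            hull = ConvexHull(poly.vertices)
            assert hull.volume == pytest.approx(vd.sizes[i], rel=1e-9)
            assert poly.measure == pytest.approx(vd.sizes[i], rel=1e-9)

    def test_mean_size_excludes_border(self, uniform_300):
        vd = flag_border_cells(build_voronoi(uniform_300), uniform_300.bounds)
        keep = ~vd.is_border
        assert vd.mean_size == pytest.approx(vd.sizes[keep].mean())
        assert 0 < keep.sum() < uniform_300.n
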
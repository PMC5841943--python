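"""Geometry primitives: orientation, hulls, normals, LEC, projection."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from puzzlecell import (
    Contour,
    Contour3D,
    convex_hull,
    largest_empty_circle,
    node_normal,
    normalize_contour,
    pca_project,
    polygon_area,
    polygon_perimeter,
    resample_contour,
    turning_angle,
)
from puzzlecell.geometry import node_normals, turning_angles

from .conftest import random_simple_polygon

SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


class TestNormalize:
    def test_cw_square_flipped_to_ccw(self):
        c = normalize_contour(Contour(SQUARE[::-1]))
        assert polygon_area(c) == pytest.approx(1.0)

    def test_ccw_triangle_unchanged(self):
        tri = Contour(np.array([[0, 0], [3, 0], [0, 4]], float))
        out = normalize_contour(tri)
        np.testing.assert_array_equal(out.points, tri.points)

    def test_duplicate_vertex_removed(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1]], float)
        assert normalize_contour(Contour(pts)).n == 4

    @pytest.mark.parametrize("bad", [
        np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float),  # bowtie
        np.array([[0, 0], [1, 0], [2, 0]], float),          # collinear
    ])
    def test_degenerate_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_contour(Contour(bad))


class TestAreaPerimeter:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)
        assert polygon_perimeter(unit_square) == pytest.approx(4.0)

    def test_right_triangle(self):
        tri = Contour(np.array([[0, 0], [3, 0], [0, 4]], float))
        assert polygon_area(tri) == pytest.approx(6.0)
        assert polygon_perimeter(tri) == pytest.approx(12.0)

    def test_fine_ngon_approximates_circle(self):
        n = 200
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c = Contour(np.column_stack([np.cos(phi), np.sin(phi)]))
        # closed forms for the regular n-gon
        assert polygon_area(c) == pytest.approx(0.5 * n * np.sin(2 * np.pi / n))
        assert polygon_area(c) == pytest.approx(np.pi, rel=1e-3)
        assert polygon_perimeter(c) == pytest.approx(2 * np.pi, rel=1e-3)


class TestConvexHull:
    def test_convex_polygon_is_its_own_hull(self, unit_square):
        h = convex_hull(unit_square)
        assert sorted(map(tuple, h.points)) == sorted(map(tuple, SQUARE))

    def test_plus_cross_hull_is_octagon(self, shapes):
        h = convex_hull(shapes["plus"])
        assert h.n == 8
        assert polygon_perimeter(h) == pytest.approx(4 + 4 * np.sqrt(2))

    def test_idempotent_and_shorter_on_random_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            c = random_simple_polygon(rng)
            h = convex_hull(c)
            h2 = convex_hull(h)
            np.testing.assert_allclose(
                np.sort(h.points, axis=0), np.sort(h2.points, axis=0)
            )
            assert polygon_perimeter(h) <= polygon_perimeter(c) + 1e-12


class TestNormalsAndTurning:
    def test_edge_midpoint_normal_points_down_on_bottom_edge(self):
        pts = np.array([[0, 0], [0.5, 0], [1, 0], [1, 1], [0, 1]], float)
        np.testing.assert_allclose(node_normal(Contour(pts), 1), [0, -1], atol=1e-12)

    def test_square_corner_normal_is_diagonal(self, unit_square):
        n = node_normal(unit_square, 0)  # corner at origin
        np.testing.assert_allclose(n, [-np.sqrt(0.5), -np.sqrt(0.5)], atol=1e-12)

    def test_circle_normals_radial(self, circle_contour):
        normals = node_normals(circle_contour)
        radial = circle_contour.points / np.linalg.norm(
            circle_contour.points, axis=1, keepdims=True
        )
        angles = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", normals, radial), -1, 1)))
        assert angles.max() < 1.0

    def test_turning_straight_zero_corner_right_angle(self):
        pts = np.array([[0, 0], [0.5, 0], [1, 0], [1, 1], [0, 1]], float)
        c = Contour(pts)
        assert turning_angle(c, 1) == pytest.approx(0.0)
        assert turning_angle(c, 2) == pytest.approx(np.pi / 2)

    def test_indentation_tip_is_negative(self, shapes):
        # deepest concave corners of the plus-cross
        t = turning_angles(shapes["plus"])
        assert (t < 0).sum() == 4
        assert t.min() == pytest.approx(-np.pi / 2)

    def test_turning_angles_sum_to_2pi_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            c = random_simple_polygon(rng)
            assert turning_angles(c).sum() == pytest.approx(2 * np.pi)


def grid_lec_oracle(c: Contour, n_grid: int = 200) -> float:
    """Brute force: max over interior lattice points of distance to contour."""
    lo = c.points.min(axis=0)
    hi = c.points.max(axis=0)
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    xx, yy = np.meshgrid(xs, ys)
    poly = c.polygon()
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
    pts = shapely.points(xx.ravel()[inside], yy.ravel()[inside])
    return float(shapely.distance(pts, poly.exterior).max())


class TestLargestEmptyCircle:
    def test_disc_lec_is_the_disc(self, circle_contour):
        lec = largest_empty_circle(circle_contour)
        assert lec.radius == pytest.approx(1.0, rel=0.01)
        np.testing.assert_allclose(lec.center, [0, 0], atol=0.02)

    @pytest.mark.parametrize("w, h, expected", [(1, 1, 0.5), (5, 1, 0.5)])
    def test_rectangles(self, w, h, expected):
        rect = Contour(np.array([[0, 0], [w, 0], [w, h], [0, h]], float))
        lec = largest_empty_circle(rect, spacing=min(w, h) / 50)
        assert lec.radius == pytest.approx(expected, rel=0.01)

    def test_matches_grid_oracle_on_random_polygons(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            c = random_simple_polygon(rng)
            lec = largest_empty_circle(c)
            oracle = grid_lec_oracle(c)
            assert lec.radius == pytest.approx(oracle, rel=0.02)

    def test_center_inside_and_disc_empty(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = random_simple_polygon(rng)
            lec = largest_empty_circle(c)
            assert c.polygon().contains(shapely.points(*lec.center))
            d = np.linalg.norm(c.points - lec.center, axis=1)
            assert d.min() >= lec.radius * (1 - 1e-6)


class TestResample:
    def test_square_quartered(self, unit_square):
        r = resample_contour(unit_square, 0.25)
        assert r.n == 16
        assert polygon_perimeter(r) == pytest.approx(4.0)

    def test_fine_contour_unchanged(self, circle_contour):
        r = resample_contour(circle_contour, 1.0)
        assert r.n == circle_contour.n

    @given(st.floats(0.05, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_perimeter_invariant(self, spacing):
        c = Contour(SQUARE * 3.0)
        assert polygon_perimeter(resample_contour(c, spacing)) == pytest.approx(
            polygon_perimeter(c), abs=1e-9
        )

    def test_rejects_nonpositive_spacing(self, unit_square):
        with pytest.raises(ValueError):
            resample_contour(unit_square, 0.0)


class TestPCAProject:
    def test_planar_contour_recovered(self):
        pts3 = np.column_stack([SQUARE, np.full(4, 3.0)])
        flat = pca_project(Contour3D(pts3))
        assert polygon_area(flat) == pytest.approx(1.0)
        assert polygon_perimeter(flat) == pytest.approx(4.0)

    def test_rotation_is_isometry(self):
        rng = np.random.default_rng(2)
        c = random_simple_polygon(rng, 30)
        pts3 = np.column_stack([c.points, np.zeros(c.n)])
        a = np.radians(30)
        rot = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        proj = pca_project(Contour3D(pts3 @ rot.T))
        assert polygon_perimeter(proj) == pytest.approx(polygon_perimeter(c), abs=1e-9)
        # all pairwise distances preserved
        d0 = np.linalg.norm(c.points[:, None] - c.points[None, :], axis=2)
        d1 = np.linalg.norm(proj.points[:, None] - proj.points[None, :], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_noisy_contour_projection_shrinks_length(self):
        rng = np.random.default_rng(3)
        c = random_simple_polygon(rng, 60)
        pts3 = np.column_stack([c.points, rng.normal(0, 0.05, c.n)])
        proj = pca_project(Contour3D(pts3))
        length3d = float(np.linalg.norm(
            np.roll(pts3, -1, axis=0) - pts3, axis=1).sum())
        assert polygon_perimeter(proj) <= length3d

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError):
            pca_project(Contour3D(line))
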
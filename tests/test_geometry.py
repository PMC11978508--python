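"""Placement, volume, collision and intersection-volume checks.

Independent oracles: explicit Euler matrices for placement, Monte-Carlo
containment and convex half-space inequalities for volumes/containment,
analytic box overlap for intersection volumes.
"""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from ccfkit.errors import (
    InvalidPlacementError,
    MethodMismatchError,
    OpenMeshError,
    UnsupportedFormatError,
)
from ccfkit.geometry import (
    AABB,
    Placement,
    TriangleMesh,
    aabb_collides,
    euler_matrix,
    intersection_volume,
    mesh_volume,
    monte_carlo_standard_error,
    place_cuboid,
    point_in_mesh,
    points_in_mesh,
)
from ccfkit.meshio import read_mesh, write_mesh

from conftest import random_box_pair


def hull_mesh(points):
    """Convex-hull surface as a TriangleMesh with outward orientation."""
    hull = ConvexHull(points)
    centroid = points[hull.vertices].mean(axis=0)
    faces = []
    for simplex in hull.simplices:
        a, b, c = points[simplex]
        normal = np.cross(b - a, c - a)
        if np.dot(normal, a - centroid) < 0:
            simplex = simplex[::-1]
        faces.append(simplex)
    # reindex onto hull vertices
    remap = {v: i for i, v in enumerate(hull.vertices)}
    verts = points[hull.vertices]
    faces = [[remap[i] for i in f] for f in faces]
    return TriangleMesh(verts, np.array(faces)), hull


class TestPlacement:
    def test_identity_placement_gives_unit_cube(self):
        mesh = place_cuboid(Placement((1, 1, 1)))
        box = mesh.aabb
        assert np.allclose(box.min_corner, 0) and np.allclose(box.max_corner, 1)
        assert len(mesh.vertices) == 8 and len(mesh.faces) == 12
        assert mesh.is_watertight

    def test_quarter_turn_swaps_aabb_axes(self):
        mesh = place_cuboid(Placement((1, 2, 3), rotation=(0, 0, 90)))
        assert np.allclose(mesh.aabb.extent, (2, 1, 3))

    def test_corners_match_explicit_rotation_matrix_oracle(self):
        dims, rot, tr = (1, 1, 1), (30, 40, 50), (0.5, -1.0, 2.0)
        mesh = place_cuboid(Placement(dims, rot, tr))

        def rx(a):
            a = np.deg2rad(a)
            return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])

        def ry(a):
            a = np.deg2rad(a)
            return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])

        def rz(a):
            a = np.deg2rad(a)
            return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])

        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        expected = corners @ (rx(30) @ ry(40) @ rz(50)).T + np.array(tr)
        got = {tuple(np.round(v, 9)) for v in mesh.vertices}
        want = {tuple(np.round(v, 9)) for v in expected}
        assert got == want

    @pytest.mark.parametrize("dims", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_non_positive_dimension_rejected(self, dims):
        with pytest.raises(InvalidPlacementError):
            Placement(dims)

    def test_placed_volume_equals_dimension_product(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            dims = tuple(rng.uniform(0.1, 5.0, 3))
            rot = tuple(rng.uniform(-180, 180, 3))
            tr = tuple(rng.uniform(-10, 10, 3))
            vol = mesh_volume(place_cuboid(Placement(dims, rot, tr)))
            assert vol == pytest.approx(np.prod(dims), rel=1e-9)


class TestMeshVolume:
    def test_unit_cube_volume(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0)

    def test_box_volume(self):
        assert mesh_volume(place_cuboid(Placement((2, 3, 4)))) == pytest.approx(24.0)

    def test_hull_volume_matches_monte_carlo_containment(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 2, size=(50, 3))
        mesh, hull = hull_mesh(pts)
        vol = mesh_volume(mesh)
        box = mesh.aabb
        samples = rng.uniform(box.min_corner, box.max_corner, size=(10**6, 3))
        inside = np.all(
            samples @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1
        )
        mc = inside.mean() * box.volume
        assert vol == pytest.approx(mc, rel=0.01)
        assert vol == pytest.approx(hull.volume, rel=1e-9)

    def test_open_mesh_rejected(self, unit_cube):
        open_mesh = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(OpenMeshError):
            mesh_volume(open_mesh)


class TestAabb:
    def test_overlapping(self):
        a = AABB(np.zeros(3), np.ones(3))
        b = AABB(np.full(3, 0.5), np.full(3, 1.5))
        assert aabb_collides(a, b)

    def test_disjoint(self):
        a = AABB(np.zeros(3), np.ones(3))
        b = AABB(np.full(3, 2.0), np.full(3, 3.0))
        assert not aabb_collides(a, b)

    def test_face_touching_counts_as_collision(self):
        a = AABB(np.zeros(3), np.ones(3))
        b = AABB(np.array([1.0, 0.0, 0.0]), np.array([2.0, 1.0, 1.0]))
        assert aabb_collides(a, b) and aabb_collides(b, a)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError):
            AABB(np.ones(3), np.zeros(3))


class TestPointInMesh:
    def test_cube_center_inside_far_point_outside(self, unit_cube):
        assert point_in_mesh(unit_cube, (0.5, 0.5, 0.5))
        assert not point_in_mesh(unit_cube, (10, 10, 10))

    def test_matches_halfspace_oracle_on_convex_hull(self):
        rng = np.random.default_rng(3)
        mesh, hull = hull_mesh(rng.uniform(-1, 1, size=(50, 3)))
        pts = rng.uniform(-1.2, 1.2, size=(1000, 3))
        oracle = np.all(pts @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1)
        assert (points_in_mesh(mesh, pts, seed=5) == oracle).all()

    def test_rotated_box_matches_halfspace_oracle(self):
        mesh = place_cuboid(Placement((1, 2, 0.5), (30, 40, 50), (0.2, 0.3, -0.1)))
        hull = ConvexHull(mesh.vertices)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1, 3, size=(2000, 3))
        oracle = np.all(pts @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1)
        assert (points_in_mesh(mesh, pts, seed=6) == oracle).all()


class TestIntersectionVolume:
    def test_offset_unit_cubes(self, unit_cube):
        other = place_cuboid(Placement((1, 1, 1), translation=(0.5, 0, 0)))
        for method in ("auto", "exact_box", "grid", "monte_carlo"):
            vol = intersection_volume(unit_cube, other, method=method, seed=1)
            assert vol == pytest.approx(0.5, rel=0.02)

    def test_block_inside_structure_returns_block_volume(self):
        block = place_cuboid(Placement((0.5, 0.5, 0.5), translation=(1, 1, 1)))
        big = place_cuboid(Placement((10, 10, 10), translation=(-2, -2, -2)))
        assert intersection_volume(block, big) == pytest.approx(0.125, rel=1e-9)

    def test_disjoint_is_zero(self, unit_cube):
        far = place_cuboid(Placement((1, 1, 1), translation=(5, 5, 5)))
        assert intersection_volume(unit_cube, far) == 0.0

    def test_exact_box_on_rotated_mesh_rejected(self, unit_cube):
        rot = place_cuboid(Placement((1, 1, 1), rotation=(0, 0, 45)))
        with pytest.raises(MethodMismatchError):
            intersection_volume(unit_cube, rot, method="exact_box")

    def test_rotated_cube_monte_carlo_agrees_with_fine_grid(self, unit_cube):
        rot = place_cuboid(Placement((1, 1, 1), rotation=(0, 0, 45), translation=(0.5, -0.2, 0)))
        samples = 200_000
        mc = intersection_volume(unit_cube, rot, method="monte_carlo",
                                 resolution_or_samples=samples, seed=9)
        grid = intersection_volume(unit_cube, rot, method="grid", resolution_or_samples=200)
        box = unit_cube.aabb.intersection(rot.aabb)
        se = monte_carlo_standard_error(mc, box.volume, samples)
        assert abs(mc - grid) < 3 * se + 1e-4  # grid itself carries O(h) bias

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            a, b, _ = random_box_pair(rng)
            rot = place_cuboid(Placement((1, 1, 1), tuple(rng.uniform(0, 90, 3)),
                                         tuple(rng.uniform(0, 2, 3))))
            for x, y in [(a, b), (a, rot)]:
                v1 = intersection_volume(x, y, method="grid", resolution_or_samples=32)
                v2 = intersection_volume(y, x, method="grid", resolution_or_samples=32)
                assert v1 == pytest.approx(v2, rel=1e-9, abs=1e-12)

    def test_bounded_by_min_mesh_volume(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            a, b, _ = random_box_pair(rng)
            vol = intersection_volume(a, b, method="grid", resolution_or_samples=32)
            assert 0.0 <= vol <= min(mesh_volume(a), mesh_volume(b)) + 1e-12

    def test_grid_error_decreases_as_resolution_doubles(self):
        # z-rotated pair: the true volume is the 2D footprint intersection
        # area times the z overlap, computable exactly with shapely
        from shapely.geometry import Polygon

        a = place_cuboid(Placement((1, 1, 1)))
        b = place_cuboid(Placement((1, 1, 1), rotation=(0, 0, 30), translation=(0.4, -0.1, 0.1)))
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        foot_b = Polygon([(x, y) for x, y, _ in b.vertices[np.isclose(b.vertices[:, 2], 0.1)]])
        foot_b = foot_b.convex_hull
        analytic = square.intersection(foot_b).area * 0.9  # z overlap [0.1, 1.0]
        errors = [
            abs(intersection_volume(a, b, method="grid", resolution_or_samples=res) - analytic)
            for res in (16, 32, 64, 128)
        ]
        assert errors[3] <= errors[0]
        assert errors[3] / analytic < 0.02

    def test_grid_exact_for_axis_aligned_box_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            a, b, analytic = random_box_pair(rng)
            grid = intersection_volume(a, b, method="grid", resolution_or_samples=128)
            assert grid == pytest.approx(analytic, rel=0.02, abs=1e-12)

    def test_positive_mesh_overlap_implies_aabb_collision(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            a, b, _ = random_box_pair(rng)
            if intersection_volume(a, b, method="grid", resolution_or_samples=16) > 0:
                assert aabb_collides(a.aabb, b.aabb)


class TestMeshIO:
    def test_off_and_obj_roundtrip(self, tmp_path, unit_cube):
        mesh = place_cuboid(Placement((1, 2, 0.5), (10, 20, 30), (0.1, 0.2, 0.3)))
        for ext in ("off", "obj"):
            path = tmp_path / f"mesh.{ext}"
            write_mesh(mesh, path)
            again = read_mesh(path)
            assert np.allclose(again.vertices, mesh.vertices, atol=1e-6)
            assert mesh_volume(again) == pytest.approx(mesh_volume(mesh), rel=1e-6)

    def test_glb_recognized_but_not_parsed(self, tmp_path):
        path = tmp_path / "organ.glb"
        path.write_bytes(b"glTF")
        with pytest.raises(UnsupportedFormatError, match="GLB"):
            read_mesh(path)
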
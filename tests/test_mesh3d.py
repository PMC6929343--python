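"""Tests for generic mesh construction, mean value coordinates, deformation
and OBJ/PLY export."""

import numpy as np
import pytest
import trimesh
from shapely.geometry import Point, Polygon

from anchor3d import mesh3d as m3
from anchor3d.anchor_shapes import generate_exemplar
from anchor3d.mesh3d import (
    DeformationDegeneracyError,
    GeometryError,
    bind_mesh,
    build_generic_mesh,
    deform_mesh,
    export_mesh,
    import_mesh,
    mean_value_weights,
    mesh_violations,
)


@pytest.fixture(scope="module")
def generic():
    outline = generate_exemplar(1, 0)
    mesh = build_generic_mesh(outline)
    binding = bind_mesh(mesh, outline)
    return outline, mesh, binding


class TestBuildGenericMesh:
    @pytest.mark.parametrize("category", range(1, 9))
    def test_all_categories_produce_valid_meshes(self, category):
        outline = generate_exemplar(category, 0)
        mesh = build_generic_mesh(outline)
        assert mesh_violations(mesh, outline) == []

    def test_boundary_controls_at_z0_matching_outline(self, generic):
        outline, mesh, _ = generic
        bm = mesh.boundary_map
        assert len(bm) == 34
        assert np.abs(mesh.vertices[bm, 2]).max() < 1e-12
        assert np.allclose(mesh.vertices[bm, :2], outline.points, atol=1e-9)

    def test_thickness_bounds_z(self, generic):
        _, mesh, _ = generic
        assert np.abs(mesh.vertices[:, 2]).max() <= 6.0 + 1e-9

    def test_trimesh_agrees_on_watertightness(self, generic):
        _, mesh, _ = generic
        tm = mesh.to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.euler_number == 2


class TestMeanValueWeights:
    def test_square_center_symmetric(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        w = mean_value_weights([5, 5], sq)
        assert np.allclose(w, 0.25, atol=1e-12)

    def test_edge_midpoint_linear(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        w = mean_value_weights([5, 0], sq)
        assert np.allclose(w, [0.5, 0.5, 0, 0], atol=1e-12)

    def test_vertex_indicator(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        w = mean_value_weights([10, 10], sq)
        assert np.allclose(w, [0, 0, 1, 0], atol=1e-12)

    def test_linear_precision_on_random_interior_points(self, rng):
        outline = generate_exemplar(3, 0)
        poly = Polygon(outline.points)
        done = 0
        while done < 100:
            p = rng.uniform(5, 91, 2)
            if not poly.contains(Point(p)):
                continue
            w = mean_value_weights(p, outline.points)
            assert abs(w.sum() - 1) < 1e-9
            assert np.abs(w @ outline.points - p).max() < 1e-9
            done += 1

    def test_outside_point_rejected_by_default(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        with pytest.raises(GeometryError):
            mean_value_weights([20, 20], sq)

    def test_signed_extension_keeps_linear_precision_outside(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        p = np.array([14.0, 3.0])
        w = mean_value_weights(p, sq, allow_outside=True)
        assert abs(w.sum() - 1) < 1e-9
        assert np.abs(w @ sq - p).max() < 1e-9


class TestBindMesh:
    def test_partition_of_unity(self, generic):
        _, _, binding = generic
        assert np.abs(binding.weights.sum(axis=1) - 1).max() < 1e-9

    def test_boundary_controls_are_indicators(self, generic):
        _, mesh, binding = generic
        for j, vi in enumerate(mesh.boundary_map):
            expected = np.zeros(34)
            expected[j] = 1
            assert np.allclose(binding.weights[vi], expected, atol=1e-9)

    def test_linear_precision_reconstructs_vertices(self, generic):
        outline, mesh, binding = generic
        rec = binding.weights @ outline.points
        assert np.abs(rec - mesh.vertices[:, :2]).max() < 1e-9


class TestDeformMesh:
    def test_identity(self, generic):
        outline, mesh, binding = generic
        out = deform_mesh(mesh, binding, outline.points)
        assert np.abs(out.vertices - mesh.vertices).max() < 1e-9

    def test_translation(self, generic):
        outline, mesh, binding = generic
        out = deform_mesh(mesh, binding, outline.points + [5.0, -3.0])
        assert np.abs(out.vertices[:, 0] - (mesh.vertices[:, 0] + 5)).max() < 1e-9
        assert np.abs(out.vertices[:, 1] - (mesh.vertices[:, 1] - 3)).max() < 1e-9
        assert np.array_equal(out.vertices[:, 2], mesh.vertices[:, 2])

    def test_uniform_scale_scales_pairwise_distances(self, generic, rng):
        outline, mesh, binding = generic
        c = outline.points.mean(axis=0)
        out = deform_mesh(mesh, binding, c + 1.2 * (outline.points - c))
        idx = rng.integers(0, len(mesh.vertices), (200, 2))
        d0 = np.linalg.norm(
            mesh.vertices[idx[:, 0], :2] - mesh.vertices[idx[:, 1], :2], axis=1
        )
        d1 = np.linalg.norm(
            out.vertices[idx[:, 0], :2] - out.vertices[idx[:, 1], :2], axis=1
        )
        keep = d0 > 1e-9
        assert np.abs(d1[keep] / d0[keep] - 1.2).max() < 1e-6

    def test_topology_and_watertightness_preserved(self, generic):
        outline, mesh, binding = generic
        target = generate_exemplar(1, 42)
        out = deform_mesh(mesh, binding, target.points)
        assert np.array_equal(out.faces, mesh.faces)
        assert np.array_equal(out.boundary_map, mesh.boundary_map)
        tm = out.to_trimesh()
        assert tm.is_watertight and tm.euler_number == 2

    def test_self_intersecting_landmarks_rejected(self, generic):
        outline, mesh, binding = generic
        bad = outline.points.copy()
        bad[[5, 20]] = bad[[20, 5]]
        with pytest.raises(DeformationDegeneracyError):
            deform_mesh(mesh, binding, bad)

    def test_cross_category_deformation_lands_on_targets(self, generic):
        outline, mesh, binding = generic
        target = generate_exemplar(4, 0)
        out = deform_mesh(mesh, binding, target.points)
        assert np.allclose(
            out.vertices[mesh.boundary_map][:, :2], target.points, atol=1e-9
        )


class TestExport:
    def test_obj_round_trip(self, tmp_path, generic):
        _, mesh, _ = generic
        p = tmp_path / "anchor.obj"
        export_mesh(mesh, "obj", p)
        v, f = import_mesh(p)
        assert np.array_equal(f, mesh.faces)
        assert np.abs(v - mesh.vertices).max() < 1e-6
        n_v_lines = sum(1 for l in p.read_text().splitlines() if l.startswith("v "))
        assert n_v_lines == len(mesh.vertices)

    def test_ply_round_trip(self, tmp_path, generic):
        _, mesh, _ = generic
        p = tmp_path / "anchor.ply"
        export_mesh(mesh, "ply", p)
        v, f = import_mesh(p)
        assert np.array_equal(f, mesh.faces)
        assert np.abs(v - mesh.vertices).max() < 1e-6

    def test_reference_reader_sees_watertight_mesh(self, tmp_path, generic):
        _, mesh, _ = generic
        p = tmp_path / "anchor.obj"
        export_mesh(mesh, "obj", p)
        tm = trimesh.load(str(p), process=False)
        assert tm.is_watertight

    def test_unknown_format_rejected(self, tmp_path, generic):
        _, mesh, _ = generic
        with pytest.raises(ValueError):
            export_mesh(mesh, "stl", tmp_path / "x.stl")
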
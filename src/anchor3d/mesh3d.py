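"""Generic 3D anchor mesh: construction, binding, deformation, export.

The generic anchor model is a watertight triangle mesh whose silhouette is
the spline contour of a 34-point outline.  It is built by triangulating the
contour interior and inflating two mirrored sheets with a rounded profile
``z = +/- thickness * sqrt(d / d_max)`` (``d`` = distance to the contour),
glued along the shared z = 0 boundary ring.  The 34 point primitives are
exact boundary vertices (the ``boundary_map``).

Deformation is driven by mean value coordinates: every vertex carries 34
weights over the control polygon, and moving the controls onto predicted
landmarks moves each vertex to the weighted combination of the new control
positions.  Mean value coordinates have linear precision, so deformations
that are similarity transforms of the controls reproduce the same transform
on the whole mesh exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon

from .anchor_shapes import N_POINTS, Outline2D, ShapeError, is_simple_polygon
from .augmentation import catmull_rom_closed


class GeometryError(ValueError):
    pass


class DeformationDegeneracyError(GeometryError):
    pass


@dataclass
class AnchorMesh:
    """Watertight triangle mesh with its 34-control boundary map.

    ``vertices`` is (V, 3) with x, y in pixel units; ``faces`` is (F, 3)
    vertex indices with consistent outward orientation; ``boundary_map`` holds
    the 34 vertex indices realizing the control primitives on the z = 0 ring.
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_map: np.ndarray

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "AnchorMesh":
        return AnchorMesh(
            self.vertices.copy(), self.faces.copy(), self.boundary_map.copy()
        )


@dataclass
class ControlBinding:
    """Per-vertex mean-value weights (V x 34) over the control primitives."""

    weights: np.ndarray


# ---------------------------------------------------------------------------
# mesh invariants


def mesh_violations(mesh: AnchorMesh, outline: Outline2D | None = None) -> list[str]:
    """Check watertightness, Euler characteristic, orientation, degeneracy,
    and (optionally) boundary_map agreement with an outline."""
    problems: list[str] = []
    v, f = mesh.vertices, mesh.faces
    edges = np.sort(
        np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        n_bad = int(np.sum(counts != 2))
        problems.append(f"watertight: {n_bad} edges not shared by exactly 2 faces")
    euler = len(v) - len(uniq) + len(f)
    if euler != 2:
        problems.append(f"euler-characteristic: V-E+F = {euler}, expected 2")
    tm = mesh.to_trimesh()
    areas = tm.area_faces
    if np.any(areas <= 1e-12):
        problems.append(f"degenerate-faces: {int(np.sum(areas <= 1e-12))} zero-area")
    if not tm.is_winding_consistent:
        problems.append("orientation: winding not consistent")
    elif tm.volume < 0:
        problems.append("orientation: normals point inward")
    bm = mesh.boundary_map
    if len(bm) != N_POINTS:
        problems.append(f"boundary-map: {len(bm)} entries, expected {N_POINTS}")
    elif np.any(np.abs(v[bm, 2]) > 1e-9):
        problems.append("boundary-map: control vertices not on z = 0")
    elif outline is not None and not np.allclose(
        v[bm, :2], outline.points, atol=1e-6
    ):
        problems.append("boundary-map: control vertices do not match outline")
    return problems


# ---------------------------------------------------------------------------
# construction


def _disk_triangulation(boundary: np.ndarray, spacing: float):
    """Triangulate the interior of a closed boundary polyline.

    Returns ``(points, triangles)`` where the first ``len(boundary)`` points
    are the boundary samples in order.  Triangles are Delaunay triangles of
    boundary plus interior grid points, filtered to the polygon interior.
    """
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise GeometryError("contour polygon is not simple")
    minx, miny, maxx, maxy = poly.bounds
    safe = poly.buffer(-0.7 * spacing)
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    if not safe.is_empty:
        keep = [p for p in grid if safe.contains(Point(p))]
    else:
        keep = []
    interior = np.array(keep) if keep else np.empty((0, 2))
    pts = np.vstack([boundary, interior]) if len(interior) else boundary.copy()
    tri = Delaunay(pts)
    centroids = pts[tri.simplices].mean(axis=1)
    inside = np.array([poly.contains(Point(c)) for c in centroids])
    # drop slivers whose area is numerically zero
    p0 = pts[tri.simplices[:, 0]]
    p1 = pts[tri.simplices[:, 1]]
    p2 = pts[tri.simplices[:, 2]]
    area2 = np.abs(np.cross(p1 - p0, p2 - p0))
    good = inside & (area2 > 1e-9)
    return _split_boundary_chords(pts, tri.simplices[good], len(boundary))


def _split_boundary_chords(pts: np.ndarray, faces: np.ndarray, n_bnd: int):
    """Split interior edges whose endpoints are both boundary vertices.

    Such chord edges (common in thin regions like the anchor tip) would be
    shared by four faces after the two sheets are glued along the z = 0 ring.
    Inserting a midpoint vertex on each chord keeps the glued mesh manifold.
    """
    pts = pts.copy()
    faces = faces.tolist()
    for _ in range(32):
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for fi, (a, b, c) in enumerate(faces):
            for e in ((a, b), (b, c), (c, a)):
                key = (min(e), max(e))
                edge_faces.setdefault(key, []).append(fi)
        bad = [
            e
            for e, fl in edge_faces.items()
            if e[0] < n_bnd and e[1] < n_bnd and len(fl) == 2
        ]
        if not bad:
            return pts, np.asarray(faces, dtype=int)
        touched: set[int] = set()
        for a, b in bad:
            fl = edge_faces[(a, b)]
            if touched & set(fl):
                continue
            m = len(pts)
            pts = np.vstack([pts, (pts[a] + pts[b]) / 2.0])
            new_faces = []
            for fi in fl:
                tri_v = faces[fi]
                # preserve winding: substituting the on-segment midpoint for
                # either endpoint keeps the vertex order
                f1 = [m if v == b else v for v in tri_v]
                f2 = [m if v == a else v for v in tri_v]
                new_faces.append((fi, f1, f2))
            for fi, f1, f2 in new_faces:
                faces[fi] = f1
                faces.append(f2)
            touched.update(fl)
    raise GeometryError("could not eliminate boundary chord edges")


def _boundary_cycle(faces: np.ndarray) -> np.ndarray:
    """Ordered vertex cycle of the (single) boundary loop of a disk mesh."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    sorted_e = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(
        sorted_e, axis=0, return_inverse=True, return_counts=True
    )
    boundary_edges = uniq[counts == 1]
    if len(boundary_edges) == 0:
        raise GeometryError("triangulated sheet has no boundary")
    adj: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    if any(len(v) != 2 for v in adj.values()):
        raise GeometryError("boundary is not a single simple cycle (pinched sheet)")
    start = int(boundary_edges[0, 0])
    cycle = [start]
    prev, cur = -1, start
    while True:
        nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
        if nxt == start:
            break
        cycle.append(nxt)
        prev, cur = cur, nxt
        if len(cycle) > len(adj) + 1:
            raise GeometryError("boundary walk did not close")
    if len(cycle) != len(adj):
        raise GeometryError("boundary has more than one loop")
    return np.array(cycle)


def build_generic_mesh(
    outline: Outline2D, thickness: float = 6.0, refinement: float = 2.0
) -> AnchorMesh:
    """Build the watertight generic anchor mesh from an outline.

    The spline contour interior is triangulated at the target edge length
    ``refinement``; two mirrored sheets with profile
    ``z = +/- thickness * sqrt(d/d_max)`` share the z = 0 boundary ring.
    The 34 control primitives are exact boundary vertices.
    """
    from .anchor_shapes import validate_outline

    violations = validate_outline(outline)
    if violations:
        raise ShapeError(f"outline invalid: {violations}")
    samples_per_seg = 8
    boundary = catmull_rom_closed(outline.points, samples_per_seg)
    # the spline interpolates its controls: sample k*samples_per_seg is control k
    control_rows = np.arange(N_POINTS) * samples_per_seg
    pts2d, faces2d = _disk_triangulation(boundary, refinement)
    cycle = _boundary_cycle(faces2d)
    n_bnd = len(boundary)
    if sorted(cycle) != list(range(n_bnd)):
        raise GeometryError(
            "sheet boundary does not coincide with the sampled contour"
        )

    poly = Polygon(boundary)
    n_pts = len(pts2d)
    is_boundary = np.zeros(n_pts, dtype=bool)
    is_boundary[:n_bnd] = True
    d = np.zeros(n_pts)
    ring = poly.exterior
    for i in range(n_bnd, n_pts):
        d[i] = ring.distance(Point(pts2d[i]))
    d_max = d.max() if n_pts > n_bnd else 1.0
    z = thickness * np.sqrt(np.clip(d, 0, None) / d_max) if d_max > 0 else d * 0.0

    # top sheet keeps all points; bottom sheet duplicates interior points only
    top = np.column_stack([pts2d, -z])  # -z is "up" toward the viewer (y-down frame)
    interior_idx = np.arange(n_bnd, n_pts)
    bottom_map = np.arange(n_pts)
    bottom_map[interior_idx] = n_pts + np.arange(len(interior_idx))
    bottom_vertices = np.column_stack([pts2d[interior_idx], z[interior_idx]])
    vertices = np.vstack([top, bottom_vertices])

    top_faces = faces2d
    bottom_faces = bottom_map[faces2d][:, ::-1]
    faces = np.vstack([top_faces, bottom_faces])

    mesh = AnchorMesh(
        vertices=vertices,
        faces=faces,
        boundary_map=control_rows.astype(int),
    )
    tm = mesh.to_trimesh()
    if tm.is_winding_consistent and tm.volume < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    problems = mesh_violations(mesh, outline)
    if problems:
        raise GeometryError(f"generic mesh construction failed: {problems}")
    return mesh


# ---------------------------------------------------------------------------
# mean value coordinates


def mean_value_weights(
    point: np.ndarray, polygon: np.ndarray, allow_outside: bool = False
) -> np.ndarray:
    """Mean value coordinates of ``point`` w.r.t. a closed simple polygon.

    Points coinciding with a polygon vertex get that vertex's indicator; points
    on an edge get the linear interpolation of the edge endpoints.  Interior
    points get the classic positive mean-value weights; with
    ``allow_outside=True`` the signed (Hormann-Floater) extension to the whole
    plane is returned instead of raising for exterior points.
    """
    p = np.asarray(point, dtype=float)
    v = np.asarray(polygon, dtype=float)
    n = len(v)
    s = v - p
    r = np.linalg.norm(s, axis=1)

    hit = np.where(r < 1e-12)[0]
    if hit.size:
        w = np.zeros(n)
        w[hit[0]] = 1.0
        return w

    s_next = np.roll(s, -1, axis=0)
    r_next = np.roll(r, -1)
    cross = s[:, 0] * s_next[:, 1] - s[:, 1] * s_next[:, 0]
    dot = (s * s_next).sum(axis=1)

    on_edge = np.where((np.abs(cross) < 1e-9 * r * r_next) & (dot < 0))[0]
    if on_edge.size:
        i = int(on_edge[0])
        j = (i + 1) % n
        w = np.zeros(n)
        t = r[i] / (r[i] + r[j])
        w[i] = 1.0 - t
        w[j] = t
        return w

    if not allow_outside and not Polygon(v).covers(Point(p)):
        raise GeometryError(f"point {tuple(p)} lies outside the control polygon")

    # tan(alpha_i / 2) with the signed angle alpha_i at edge (i, i+1)
    tan_half = (r * r_next - dot) / cross
    w = (np.roll(tan_half, 1) + tan_half) / r
    return w / w.sum()


def bind_mesh(mesh: AnchorMesh, outline: Outline2D) -> ControlBinding:
    """Mean-value weights of every vertex's (x, y) w.r.t. the 34 controls."""
    controls = outline.points
    weights = np.empty((len(mesh.vertices), N_POINTS))
    for i, vert in enumerate(mesh.vertices):
        weights[i] = mean_value_weights(vert[:2], controls, allow_outside=True)
    return ControlBinding(weights)


def deform_mesh(
    mesh: AnchorMesh, binding: ControlBinding, landmarks: np.ndarray
) -> AnchorMesh:
    """Deform the mesh by moving its 34 controls onto ``landmarks``.

    Every vertex's new (x, y) is its weight row times the landmark positions;
    z, faces and the boundary map are unchanged.  The landmark polygon must be
    simple; a self-intersecting prediction is reported, not silently used.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.shape != (N_POINTS, 2):
        raise ValueError(f"expected {N_POINTS} landmark pairs, got {lm.shape}")
    if not is_simple_polygon(lm):
        raise DeformationDegeneracyError(
            "landmark polygon is self-intersecting or degenerate"
        )
    out = mesh.copy()
    out.vertices[:, :2] = binding.weights @ lm
    return out


# ---------------------------------------------------------------------------
# export


def export_mesh(mesh: AnchorMesh, fmt: str, path) -> None:
    """Write the mesh as Wavefront OBJ or ASCII PLY.

    OBJ uses ``v``/``f`` records with 1-based indices and 6-decimal
    coordinates; PLY is ASCII with the standard vertex/face header.
    """
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    v, f = mesh.vertices, mesh.faces
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "obj":
            for x, y, z in v:
                fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
            for a, b, c in f + 1:
                fh.write(f"f {a} {b} {c}\n")
        else:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(v)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                f"element face {len(f)}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for x, y, z in v:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            for a, b, c in f:
                fh.write(f"3 {a} {b} {c}\n")


def import_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an OBJ/PLY file back via trimesh; returns (vertices, faces)."""
    tm = trimesh.load(str(path), process=False)
    return np.asarray(tm.vertices), np.asarray(tm.faces)
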
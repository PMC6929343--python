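"""Parametric 2D anchor outlines.

A monogenean haptoral anchor is drawn here as a closed outline through 34
ordered control points ("point primitives").  The same 34 points serve three
roles throughout the pipeline: morphing correspondences during augmentation,
landmark annotations for the regressor, and deformation controls for the
generic 3D mesh.  Index semantics are fixed so that corresponding indices are
anatomically corresponding across shapes:

* indices 0-9   -- the base, traced across the root region (two root lobes),
* indices 10-21 -- the outer side of the curved shaft (fan-like extrusions,
                   where present, bulge within this range),
* indices 22-33 -- the recurved point: outer approach, the tip itself, and the
                   inner return toward the base (hooks, where present, sit on
                   the outer approach).

Coordinates are continuous image coordinates on a 96x96 canvas: origin at the
top-left, x rightward, y downward, domain [0, 96) x [0, 96).  Outlines are
oriented counter-clockwise as seen on screen with y pointing down (which is a
negative shoelace sum in the usual y-up formula).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

CANVAS_SIZE = 96
N_POINTS = 34
N_CATEGORIES = 8

# index ranges of the anatomical regions along the ordered contour
BASE_RANGE = range(0, 10)
SHAFT_RANGE = range(10, 22)
POINT_RANGE = range(22, 34)


@dataclass(frozen=True)
class PointPrimitive:
    """One 2D control point in continuous image coordinates (pixels)."""

    x: float
    y: float


@dataclass
class Outline2D:
    """An ordered closed contour of exactly 34 point primitives.

    Parameters
    ----------
    points
        ``(34, 2)`` float array of (x, y) image coordinates.
    category
        Shape-category identifier in 1..8.
    """

    points: np.ndarray
    category: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    def copy(self) -> "Outline2D":
        return Outline2D(self.points.copy(), self.category)

    @property
    def xy(self) -> np.ndarray:
        return self.points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Outline2D):
            return NotImplemented
        return self.category == other.category and np.array_equal(
            self.points, other.points
        )


@dataclass(frozen=True)
class ShapeCategoryParams:
    """Dimensional parameters of one anchor shape category.

    Lengths are in pixels (on the pre-fit construction scale), angles in
    degrees.  ``extrusion_size`` and ``hook_size`` of 0 disable the feature.
    """

    base_width: float
    root_length: float
    shaft_length: float
    shaft_curvature: float
    point_recurve_angle: float
    extrusion_size: float = 0.0
    hook_size: float = 0.0


#: One preset per shape category.  Categories 5 and 7 carry a fan-like
#: extrusion on the outer shaft, category 8 a hook near the tip -- the
#: features that are hardest for the downstream deformation to reproduce.
CATEGORY_PRESETS: dict[int, ShapeCategoryParams] = {
    1: ShapeCategoryParams(16.0, 7.0, 52.0, 35.0, 80.0),
    2: ShapeCategoryParams(13.0, 5.0, 58.0, 20.0, 95.0),
    3: ShapeCategoryParams(18.0, 9.0, 48.0, 45.0, 70.0),
    4: ShapeCategoryParams(15.0, 6.0, 55.0, 55.0, 85.0),
    5: ShapeCategoryParams(17.0, 8.0, 50.0, 40.0, 75.0, extrusion_size=6.0),
    6: ShapeCategoryParams(14.0, 7.0, 60.0, 30.0, 100.0),
    7: ShapeCategoryParams(19.0, 10.0, 46.0, 50.0, 65.0, extrusion_size=8.0),
    8: ShapeCategoryParams(15.0, 6.0, 54.0, 38.0, 90.0, hook_size=5.0),
}


class ShapeError(ValueError):
    """Raised when a shape operation receives or produces invalid geometry."""


class DegenerateShapeError(ShapeError):
    """Raised when bounded retries cannot produce a valid outline."""


# ---------------------------------------------------------------------------
# geometry helpers


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (y-up sign convention).

    Under the image convention used here (y down), a visually
    counter-clockwise contour has *negative* shoelace area.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_area(points: np.ndarray) -> float:
    """Absolute enclosed area of the closed polygon through ``points``."""
    return abs(signed_area(points))


def is_ccw_image(points: np.ndarray) -> bool:
    """True if the contour is counter-clockwise on a y-down canvas."""
    return signed_area(points) < 0


def is_simple_polygon(points: np.ndarray) -> bool:
    """True if the closed polygon has no self-intersections and positive area."""
    poly = Polygon(np.asarray(points, dtype=float))
    return poly.is_valid and poly.area > 0


def _crossing_pair(points: np.ndarray) -> tuple[int, int] | None:
    """Find one pair of properly crossing edges, or None (O(n^2) scan)."""
    p = np.asarray(points, dtype=float)
    n = len(p)

    def seg(i):
        return p[i], p[(i + 1) % n]

    def cross2(u, v):
        return u[0] * v[1] - u[1] * v[0]

    for i in range(n):
        a, b = seg(i)
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            c, d = seg(j)
            d1 = cross2(b - a, c - a)
            d2 = cross2(b - a, d - a)
            d3 = cross2(d - c, a - c)
            d4 = cross2(d - c, b - c)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return i, j
    return None


# ---------------------------------------------------------------------------
# validation


def validate_outline(outline: Outline2D) -> list[str]:
    """Check every outline invariant; return a list of violation messages.

    An empty list means the outline is valid.  Violations are data, not
    exceptions: each message names the failed invariant and, where it applies,
    the offending point or edge index.
    """
    violations: list[str] = []
    pts = np.asarray(outline.points, dtype=float)

    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != N_POINTS:
        count = pts.shape[0] if pts.ndim == 2 else -1
        violations.append(f"point-count: expected {N_POINTS}, found {count}")
        return violations

    if not (1 <= int(outline.category) <= N_CATEGORIES):
        violations.append(f"category: {outline.category} not in 1..{N_CATEGORIES}")

    if not np.all(np.isfinite(pts)):
        idx = int(np.argwhere(~np.isfinite(pts))[0, 0])
        violations.append(f"non-finite coordinate at index {idx}")
        return violations

    out = np.argwhere((pts < 0) | (pts >= CANVAS_SIZE))
    if out.size:
        violations.append(f"out-of-canvas point at index {int(out[0, 0])}")

    if polygon_area(pts) <= 0:
        violations.append("zero-area: polygon has no enclosed area")
        return violations

    if not is_simple_polygon(pts):
        pair = _crossing_pair(pts)
        where = f" (edges {pair[0]} and {pair[1]})" if pair else ""
        violations.append(f"self-intersection{where}")
        return violations

    if not is_ccw_image(pts):
        violations.append("orientation: contour is not counter-clockwise (y-down)")

    return violations


# ---------------------------------------------------------------------------
# construction


def _gauss_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _build_outline(params: ShapeCategoryParams) -> np.ndarray:
    """Construct the 34 points in a local y-down frame from shape parameters.

    The anchor is swept along a spine whose heading turns by
    ``shaft_curvature`` degrees over the shaft and a further
    ``point_recurve_angle`` degrees over the distal point section, with a
    width profile that tapers from ``base_width`` at the base to zero at the
    tip.  Roots are two downward lobes on the base edge.
    """
    n_fine = 400
    point_len = 0.40 * params.shaft_length
    total_len = params.shaft_length + point_len
    u = np.linspace(0.0, 1.0, n_fine)
    s = u * total_len

    # heading: start pointing "up" (-y); turn progressively to the +x side
    shaft_frac = params.shaft_length / total_len
    turn = np.where(
        u <= shaft_frac,
        np.radians(params.shaft_curvature) * (u / shaft_frac),
        np.radians(params.shaft_curvature)
        + np.radians(params.point_recurve_angle)
        * ((u - shaft_frac) / (1 - shaft_frac)),
    )
    heading = -np.pi / 2 + turn
    dx = np.cos(heading)
    dy = np.sin(heading)
    ds = np.gradient(s)
    spine = np.column_stack(
        [np.cumsum(dx * ds) - dx[0] * ds[0], np.cumsum(dy * ds) - dy[0] * ds[0]]
    )

    # outward normal (rotate heading by -90 deg in the y-down frame)
    normal = np.column_stack([dy, -dx])

    # half-width profile: full at base, gently narrowing, zero at the tip
    w0 = params.base_width / 2.0
    width = w0 * (0.35 + 0.65 * (1 - u)) * np.sqrt(np.clip(1 - u**1.8, 0, 1))

    def outer(uq: np.ndarray) -> np.ndarray:
        i = np.clip(np.round(uq * (n_fine - 1)).astype(int), 0, n_fine - 1)
        return spine[i] + normal[i] * width[i, None]

    def inner(uq: np.ndarray) -> np.ndarray:
        i = np.clip(np.round(uq * (n_fine - 1)).astype(int), 0, n_fine - 1)
        return spine[i] - normal[i] * width[i, None]

    # base edge: inner corner -> outer corner with two root lobes (10 pts)
    tau = np.linspace(0.0, 1.0, 10)
    b_inner = inner(np.array([0.0]))[0]
    b_outer = outer(np.array([0.0]))[0]
    root = params.root_length * (
        _gauss_bump(tau, 0.25, 0.12) + _gauss_bump(tau, 0.75, 0.12)
    )
    base = b_inner[None, :] + tau[:, None] * (b_outer - b_inner)[None, :]
    base[:, 1] += root  # roots extend downward (+y)

    # outer shaft (12 pts), with optional fan-like extrusion bulge
    u_shaft = np.linspace(0.07, 0.66, 12)
    shaft = outer(u_shaft)
    if params.extrusion_size > 0:
        i = np.clip(np.round(u_shaft * (n_fine - 1)).astype(int), 0, n_fine - 1)
        bulge = params.extrusion_size * _gauss_bump(u_shaft, 0.30, 0.11)
        shaft += normal[i] * bulge[:, None]

    # recurved point: outer approach (3), tip (1), inner return (8)
    u_outer = np.array([0.76, 0.86, 0.94])
    outer_pt = outer(u_outer)
    if params.hook_size > 0:
        i = np.clip(np.round(u_outer * (n_fine - 1)).astype(int), 0, n_fine - 1)
        barb = params.hook_size * np.array([0.35, 1.0, 0.45])
        outer_pt += normal[i] * barb[:, None]
    tip = spine[-1][None, :]
    u_inner = np.array([0.88, 0.76, 0.64, 0.52, 0.41, 0.30, 0.19, 0.09])
    inner_pt = inner(u_inner)

    pts = np.vstack([base, shaft, outer_pt, tip, inner_pt])
    assert pts.shape == (N_POINTS, 2)
    return pts


def _fit_to_canvas(pts: np.ndarray, margin: float = 10.0) -> np.ndarray:
    """Isotropically scale and centre the point set on the 96x96 canvas."""
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi - lo))
    scale = (CANVAS_SIZE - 2 * margin) / span
    centred = (pts - (lo + hi) / 2.0) * scale
    return centred + CANVAS_SIZE / 2.0


def generate_exemplar(category: int, seed: int) -> Outline2D:
    """Generate a deterministic exemplar outline of the given shape category.

    For a fixed ``(category, seed)`` the result is bit-identical across
    calls.  Different seeds jitter the category's preset parameters by a few
    percent, giving distinct but same-category individuals.
    """
    if category not in CATEGORY_PRESETS:
        raise ShapeError(f"unknown shape category: {category!r} (expected 1..8)")
    params = CATEGORY_PRESETS[category]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(category), 17]))
    jitter = rng.uniform(0.95, 1.05, size=7)
    jittered = ShapeCategoryParams(
        base_width=params.base_width * jitter[0],
        root_length=params.root_length * jitter[1],
        shaft_length=params.shaft_length * jitter[2],
        shaft_curvature=params.shaft_curvature * jitter[3],
        point_recurve_angle=params.point_recurve_angle * jitter[4],
        extrusion_size=params.extrusion_size * jitter[5],
        hook_size=params.hook_size * jitter[6],
    )
    pts = _fit_to_canvas(_build_outline(jittered))
    if not is_ccw_image(pts):
        # construction is oriented by design; guard against parameter extremes
        pts = pts[::-1].copy()
    outline = Outline2D(pts, category)
    violations = validate_outline(outline)
    if violations:
        raise DegenerateShapeError(
            f"exemplar construction failed for category {category}: {violations}"
        )
    return outline


def _smooth_field(
    rng: np.random.Generator, n: int, magnitude: float, window: int = 7
) -> np.ndarray:
    """Smooth random displacement field along a closed contour.

    Independent Gaussian draws per point are circularly smoothed along the
    contour, then rescaled so the largest point displacement equals
    ``magnitude``.  Smoothness keeps neighbouring points moving coherently so
    the perturbed contour stays a plausible, simple outline.
    """
    raw = rng.normal(size=(n, 2))
    kernel = np.exp(-0.5 * (np.arange(window) - window // 2) ** 2 / 1.5**2)
    kernel /= kernel.sum()
    smooth = np.empty_like(raw)
    for k in range(2):
        padded = np.concatenate([raw[-(window // 2):, k], raw[:, k], raw[: window // 2, k]])
        smooth[:, k] = np.convolve(padded, kernel, mode="valid")
    norms = np.linalg.norm(smooth, axis=1)
    peak = norms.max()
    if peak == 0:
        return np.zeros((n, 2))
    return smooth * (magnitude / peak)


def perturb_exemplar(
    outline: Outline2D, magnitude: float, seed: int, max_retries: int = 64
) -> Outline2D:
    """Displace every point by a smooth random field of bounded amplitude.

    No point moves farther than ``magnitude`` pixels.  The displacement is
    resampled (up to ``max_retries`` times) until the perturbed outline is a
    simple in-canvas polygon.
    """
    if magnitude < 0:
        raise ShapeError("perturbation magnitude must be >= 0")
    if magnitude == 0:
        return outline.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    for _ in range(max_retries):
        disp = _smooth_field(rng, len(outline.points), magnitude)
        candidate = Outline2D(outline.points + disp, outline.category)
        if not validate_outline(candidate):
            return candidate
    raise DegenerateShapeError(
        f"could not produce a valid perturbed outline after {max_retries} tries"
    )


# ---------------------------------------------------------------------------
# CSV I/O


def write_outline_csv(outline: Outline2D, path) -> None:
    """Write the 34 points as CSV with header ``x,y`` and 6-decimal values."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y\n")
        for x, y in outline.points:
            fh.write(f"{x:.6f},{y:.6f}\n")


def read_outline_csv(path, category: int = 1) -> Outline2D:
    """Read a 34-row ``x,y`` CSV (header optional) as an outline."""
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if line_no == 1 and not _is_number(cells[0]):
                continue  # header
            if len(cells) < 2 or not (_is_number(cells[0]) and _is_number(cells[1])):
                raise ShapeError(f"non-numeric cell at row {line_no} of {path}")
            rows.append((float(cells[0]), float(cells[1])))
    if len(rows) != N_POINTS:
        raise ShapeError(f"expected {N_POINTS} points, found {len(rows)} in {path}")
    return Outline2D(np.array(rows, dtype=float), category)


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False
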
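"""Shape-interpolation data augmentation.

Training illustrations are synthesized by morphing: a source outline is
linearly interpolated toward a perturbed target outline, 24 intermediate
shapes are captured per morph, each is randomly rotated and scaled on the
96x96 canvas, rasterized to a grayscale pixel array, and stored together with
the transformed 34-point landmark annotation.  Because the pixel array and
the annotation are produced from the same transformed outline, re-rasterizing
the stored coordinates reproduces the stored pixels bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .anchor_shapes import (
    CANVAS_SIZE,
    N_POINTS,
    DegenerateShapeError,
    Outline2D,
    ShapeError,
    generate_exemplar,
    perturb_exemplar,
    polygon_area,
    validate_outline,
)

#: Number of intermediate shapes captured per morph sequence.
DEFAULT_N_FRAMES = 24

#: Default amplitude (pixels) of the smooth perturbation that turns a source
#: exemplar into its morph target.
DEFAULT_PERTURB_PX = 4.0

SUPERSAMPLE = 4
SPLINE_SAMPLES_PER_SEGMENT = 8


@dataclass(frozen=True)
class CanvasSpec:
    """The standardized 96x96 grayscale canvas: dark shape on white ground."""

    width: int = CANVAS_SIZE
    height: int = CANVAS_SIZE
    background_intensity: int = 255
    foreground_intensity: int = 0
    margin: float = 3.0

    def __post_init__(self) -> None:
        if self.width != CANVAS_SIZE or self.height != CANVAS_SIZE:
            raise ValueError(f"canvas must be {CANVAS_SIZE}x{CANVAS_SIZE}")
        for v in (self.background_intensity, self.foreground_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must be in [0, 255]")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class SyntheticRecord:
    """One training document: name, category, pixels, landmark annotation."""

    name: str
    shape_id: int
    pixels: np.ndarray  # (9216,) uint8-valued ints
    coordinate_x: np.ndarray  # (34,)
    coordinate_y: np.ndarray  # (34,)

    def validate(self) -> list[str]:
        problems = []
        if not self.name or len(self.name) > 100:
            problems.append("name")
        px = np.asarray(self.pixels)
        if px.shape != (CANVAS_SIZE * CANVAS_SIZE,) or px.min() < 0 or px.max() > 255:
            problems.append("pixels")
        cx, cy = np.asarray(self.coordinate_x), np.asarray(self.coordinate_y)
        if cx.shape != (N_POINTS,) or cy.shape != (N_POINTS,):
            problems.append("landmarks")
        elif (
            cx.min() < 0 or cx.max() >= CANVAS_SIZE
            or cy.min() < 0 or cy.max() >= CANVAS_SIZE
        ):
            problems.append("landmarks")
        return problems


class InterpolationDegeneracyError(ShapeError):
    pass


class TransformPlacementError(ShapeError):
    pass


# ---------------------------------------------------------------------------
# morphing


def interpolate_shapes(
    source: Outline2D, target: Outline2D, n_frames: int = DEFAULT_N_FRAMES
) -> list[Outline2D]:
    """Capture ``n_frames`` shapes while morphing ``source`` into ``target``.

    Frame i (1-based) places every point at
    ``(1 - t_i) * P_source + t_i * P_target`` with ``t_i = i / (n_frames + 1)``,
    i.e. strictly between the endpoints, preserving index-wise correspondence.
    """
    if source.category != target.category:
        raise ShapeError(
            f"category mismatch: source {source.category} vs target {target.category}"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for label, o in (("source", source), ("target", target)):
        v = validate_outline(o)
        if v:
            raise ShapeError(f"{label} outline invalid: {v}")
    frames = []
    for i in range(1, n_frames + 1):
        t = i / (n_frames + 1)
        pts = (1 - t) * source.points + t * target.points
        frame = Outline2D(pts, source.category)
        violations = validate_outline(frame)
        if violations:
            raise InterpolationDegeneracyError(
                f"interpolated frame {i} invalid: {violations}"
            )
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# similarity transforms


def apply_similarity(
    outline: Outline2D,
    angle_deg: float,
    scale: float,
    center: np.ndarray | None = None,
) -> Outline2D:
    """Rotate by ``angle_deg`` and scale isotropically about ``center``.

    ``center`` defaults to the outline centroid (mean of the 34 points).
    """
    pts = outline.points
    c = pts.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    theta = np.radians(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    new = c + scale * ((pts - c) @ rot.T)
    return Outline2D(new, outline.category)


def max_inscribed_scale(
    points: np.ndarray, center: np.ndarray, margin: float
) -> float:
    """Largest isotropic scale about ``center`` keeping all points within
    ``[margin, 96 - margin)`` in both axes."""
    lo, hi = margin, CANVAS_SIZE - margin
    d = points - center
    limits = []
    for k in range(2):
        pos = d[:, k] > 1e-12
        neg = d[:, k] < -1e-12
        if pos.any():
            limits.append(((hi - center[k]) / d[pos, k]).min())
        if neg.any():
            limits.append(((lo - center[k]) / d[neg, k]).min())
    if center[0] < lo or center[0] >= hi or center[1] < lo or center[1] >= hi:
        raise TransformPlacementError("outline centroid outside usable canvas")
    return float(min(limits)) if limits else 1.0


def random_similarity_transform(
    outline: Outline2D,
    rng: np.random.Generator,
    canvas: CanvasSpec = CanvasSpec(),
    max_retries: int = 64,
) -> Outline2D:
    """Apply a random rotation and scale about the outline centroid.

    The rotation angle is uniform on [0, 360) degrees; the scale is uniform on
    [0.6, 1.0] relative to the largest scale that keeps the rotated shape
    inside the canvas minus its margin.  Draws are resampled (bounded retries)
    if the placed outline fails validation.
    """
    violations = validate_outline(outline)
    if violations:
        raise ShapeError(f"input outline invalid: {violations}")
    for _ in range(max_retries):
        angle = float(rng.uniform(0.0, 360.0))
        rel_scale = float(rng.uniform(0.6, 1.0))
        rotated = apply_similarity(outline, angle, 1.0)
        s_max = max_inscribed_scale(
            rotated.points, outline.points.mean(axis=0), canvas.margin
        )
        candidate = apply_similarity(outline, angle, rel_scale * s_max)
        if not validate_outline(candidate):
            return candidate
    raise TransformPlacementError(
        f"no valid similarity placement after {max_retries} draws"
    )


# ---------------------------------------------------------------------------
# rasterization


def catmull_rom_closed(
    points: np.ndarray, samples_per_segment: int = SPLINE_SAMPLES_PER_SEGMENT
) -> np.ndarray:
    """Densify a closed contour with a uniform Catmull-Rom spline.

    The spline interpolates every control point; each of the n segments
    contributes ``samples_per_segment`` samples (the segment start included,
    the end excluded), giving ``n * samples_per_segment`` points in total.
    """
    p = np.asarray(points, dtype=float)
    n = len(p)
    p0 = np.roll(p, 1, axis=0)
    p1 = p
    p2 = np.roll(p, -1, axis=0)
    p3 = np.roll(p, -2, axis=0)
    t = (np.arange(samples_per_segment) / samples_per_segment)[None, :, None]
    t2, t3 = t * t, t * t * t
    seg = 0.5 * (
        (2 * p1[:, None, :])
        + (-p0 + p2)[:, None, :] * t
        + (2 * p0 - 5 * p1 + 4 * p2 - p3)[:, None, :] * t2
        + (-p0 + 3 * p1 - 3 * p2 + p3)[:, None, :] * t3
    )
    return seg.reshape(n * samples_per_segment, 2)


def rasterize(outline: Outline2D, canvas: CanvasSpec = CanvasSpec()) -> np.ndarray:
    """Render the outline as a flattened 96x96 grayscale array (9216 ints).

    The 34-point contour is smoothed with a closed uniform Catmull-Rom spline
    (8 samples per segment), filled at 4x supersampling, box-downsampled, and
    flattened row-major.  Foreground is dark on a light background.
    """
    pts = np.asarray(outline.points, dtype=float)
    if pts.min() < 0 or pts.max() >= CANVAS_SIZE:
        raise ShapeError("outline extends outside the canvas")
    dense = catmull_rom_closed(pts)
    size = CANVAS_SIZE * SUPERSAMPLE
    img = Image.new("L", (size, size), canvas.background_intensity)
    if polygon_area(dense) < 1e-9:  # nothing to fill
        return np.full(CANVAS_SIZE * CANVAS_SIZE, canvas.background_intensity, np.int64)
    # supersampled pixel-centre grid: image coord v maps to index v*S - 0.5
    vertices = [tuple(p) for p in dense * SUPERSAMPLE - 0.5]
    ImageDraw.Draw(img).polygon(vertices, fill=canvas.foreground_intensity)
    arr = np.asarray(img, dtype=float)
    down = arr.reshape(CANVAS_SIZE, SUPERSAMPLE, CANVAS_SIZE, SUPERSAMPLE).mean(
        axis=(1, 3)
    )
    return np.rint(down).astype(np.int64).reshape(-1)


def record_to_image(record: SyntheticRecord):
    """Return the record's pixels as a Pillow 8-bit grayscale image."""
    from PIL import Image

    arr = np.asarray(record.pixels, dtype=np.uint8).reshape(CANVAS_SIZE, CANVAS_SIZE)
    return Image.fromarray(arr, mode="L")


def export_record_png(record: SyntheticRecord, path) -> None:
    """Write the record's pixel array as a lossless 96x96 grayscale PNG."""
    record_to_image(record).save(path, format="PNG")


# ---------------------------------------------------------------------------
# dataset generation


def _category_stream(category: int, seed: int, n_frames: int, perturb_px: float,
                     canvas: CanvasSpec):
    """Yield transformed morph frames for one category, batch after batch."""
    batch = 0
    while True:
        ss = np.random.SeedSequence([int(seed), int(category), batch, 101])
        rng = np.random.default_rng(ss)
        src_seed = int(rng.integers(0, 2**31 - 1))
        source = generate_exemplar(category, src_seed)
        target = perturb_exemplar(source, perturb_px, int(rng.integers(0, 2**31 - 1)))
        frames = interpolate_shapes(source, target, n_frames)
        for frame_idx, frame in enumerate(frames):
            placed = random_similarity_transform(frame, rng, canvas)
            yield batch, frame_idx, placed
        batch += 1


def generate_dataset(
    n_total: int,
    seed: int,
    categories: list[int] | None = None,
    canvas: CanvasSpec = CanvasSpec(),
    n_frames: int = DEFAULT_N_FRAMES,
    perturb_px: float = DEFAULT_PERTURB_PX,
) -> list[SyntheticRecord]:
    """Generate ``n_total`` annotated synthetic illustrations.

    Categories are assigned round-robin for class balance.  Each category
    consumes its own sequence of morph batches (source exemplar -> perturbed
    target -> ``n_frames`` interpolated shapes), every frame is randomly
    rotated/scaled and rasterized, and the transformed 34 coordinates are
    stored as the annotation.  Fully deterministic for a fixed seed.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    cats = list(categories) if categories is not None else list(range(1, 9))
    streams = {c: _category_stream(c, seed, n_frames, perturb_px, canvas) for c in cats}
    records: list[SyntheticRecord] = []
    for i in range(n_total):
        cat = cats[i % len(cats)]
        try:
            batch, frame_idx, placed = next(streams[cat])
        except ShapeError as exc:  # pragma: no cover - propagated with context
            raise type(exc)(f"record {i} (category {cat}): {exc}") from exc
        pixels = rasterize(placed, canvas)
        rec = SyntheticRecord(
            name=f"{cat}_{batch}_{frame_idx}",
            shape_id=cat,
            pixels=pixels,
            coordinate_x=placed.points[:, 0].copy(),
            coordinate_y=placed.points[:, 1].copy(),
        )
        assert not rec.validate()
        records.append(rec)
    return records
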
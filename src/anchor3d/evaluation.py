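"""Control-point vs predicted-landmark evaluation.

The pipeline is judged by how closely the landmarks the regressor predicts on
an illustration match control points annotated on the ideal positions along
the illustration's edge.  Following the original boxplot methodology, the x
and y coordinates of both point sets are summarized by five-number summaries
(min, Q1, median, Q3, max) and compared per statistic; index-wise point
metrics (mean/max Euclidean error and RMSE) sharpen the visual comparison
into machine-checkable numbers.  Index-wise metrics assume the control points
are annotated in the same order as the 34 point primitives.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .anchor_shapes import CANVAS_SIZE, N_POINTS


class EvaluationError(ValueError):
    pass


@dataclass
class ControlPointSet:
    """34 manually annotated (x, y) control points on one illustration."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_POINTS, 2):
            raise EvaluationError(
                f"expected {N_POINTS} control points, found {len(self.points)}"
            )


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary underlying one box plot."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def as_array(self) -> np.ndarray:
        return np.array([self.minimum, self.q1, self.median, self.q3, self.maximum])


@dataclass
class ComparisonReport:
    """Per-axis five-number summaries and index-wise error metrics."""

    control_x: BoxplotStats
    predicted_x: BoxplotStats
    control_y: BoxplotStats
    predicted_y: BoxplotStats
    stat_abs_diff_x: np.ndarray
    stat_abs_diff_y: np.ndarray
    mean_error: float
    max_error: float
    rmse: float

    def to_json(self, path) -> None:
        payload = {
            "control_x": asdict(self.control_x),
            "predicted_x": asdict(self.predicted_x),
            "control_y": asdict(self.control_y),
            "predicted_y": asdict(self.predicted_y),
            "stat_abs_diff_x": list(map(float, self.stat_abs_diff_x)),
            "stat_abs_diff_y": list(map(float, self.stat_abs_diff_y)),
            "mean_error": self.mean_error,
            "max_error": self.max_error,
            "rmse": self.rmse,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def to_csv(self, path) -> None:
        rows = [("statistic", "control_x", "predicted_x", "control_y", "predicted_y")]
        labels = ("minimum", "q1", "median", "q3", "maximum")
        cx, px = self.control_x.as_array(), self.predicted_x.as_array()
        cy, py = self.control_y.as_array(), self.predicted_y.as_array()
        for i, lab in enumerate(labels):
            rows.append((lab, f"{cx[i]:.6f}", f"{px[i]:.6f}", f"{cy[i]:.6f}", f"{py[i]:.6f}"))
        rows.append(("mean_error", f"{self.mean_error:.6f}", "", "", ""))
        rows.append(("max_error", f"{self.max_error:.6f}", "", "", ""))
        rows.append(("rmse", f"{self.rmse:.6f}", "", "", ""))
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerows(rows)


# ---------------------------------------------------------------------------
# I/O


def read_control_points(path) -> ControlPointSet:
    """Read a 34-row ``x,y`` CSV (header optional) of control points."""
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if line_no == 1:
                try:
                    float(cells[0])
                except ValueError:
                    continue  # header row
            try:
                rows.append((float(cells[0]), float(cells[1])))
            except (ValueError, IndexError) as exc:
                raise EvaluationError(
                    f"non-numeric cell at row {line_no} of {path}"
                ) from exc
    if len(rows) != N_POINTS:
        raise EvaluationError(f"expected {N_POINTS} control points, found {len(rows)}")
    return ControlPointSet(np.array(rows, dtype=float))


def write_control_points(points: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x,y\n")
        for x, y in np.asarray(points, dtype=float):
            fh.write(f"{x:.6f},{y:.6f}\n")


# ---------------------------------------------------------------------------
# statistics


def boxplot_stats(values) -> BoxplotStats:
    """Five-number summary with quartiles by linear interpolation of order
    statistics at positions ``1 + (n - 1) * p`` for p in {0.25, 0.5, 0.75}."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EvaluationError("cannot summarize an empty sequence")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return BoxplotStats(float(v.min()), float(q1), float(med), float(q3), float(v.max()))


def compare_point_sets(control, predicted) -> ComparisonReport:
    """Compare annotated control points with predicted landmarks.

    Produces the per-axis five-number summaries of both sets, the absolute
    per-statistic differences, and index-wise point metrics (mean and max
    Euclidean error, RMSE), assuming order correspondence of the 34 points.
    """
    cp = control.points if isinstance(control, ControlPointSet) else np.asarray(control, float)
    pp = np.asarray(predicted, dtype=float)
    if cp.shape != (N_POINTS, 2) or pp.shape != (N_POINTS, 2):
        raise EvaluationError(
            f"both point sets must have shape ({N_POINTS}, 2); "
            f"got {cp.shape} and {pp.shape}"
        )
    cx, px = boxplot_stats(cp[:, 0]), boxplot_stats(pp[:, 0])
    cy, py = boxplot_stats(cp[:, 1]), boxplot_stats(pp[:, 1])
    dist = np.linalg.norm(cp - pp, axis=1)
    return ComparisonReport(
        control_x=cx,
        predicted_x=px,
        control_y=cy,
        predicted_y=py,
        stat_abs_diff_x=np.abs(cx.as_array() - px.as_array()),
        stat_abs_diff_y=np.abs(cy.as_array() - py.as_array()),
        mean_error=float(dist.mean()),
        max_error=float(dist.max()),
        rmse=float(np.sqrt(np.mean(dist**2))),
    )


# ---------------------------------------------------------------------------
# rendering


def render_boxplots(report: ComparisonReport, path) -> None:
    """Write the control-vs-predicted box plots for both axes.

    ``.svg`` paths get a small hand-written deterministic SVG (box extents in
    a recoverable linear data-to-pixel mapping); any other extension is
    rendered with matplotlib (PNG).
    """
    path = Path(path)
    if path.suffix.lower() == ".svg":
        _render_svg(report, path)
    else:
        _render_png(report, path)


_SVG_PLOT = {"x0": 40.0, "y0": 260.0, "height": 220.0, "box_w": 40.0, "gap": 70.0}


def svg_value_to_y(value: float, vmax: float = CANVAS_SIZE) -> float:
    """Linear data->pixel mapping used by the SVG renderer (y grows up)."""
    g = _SVG_PLOT
    return g["y0"] - g["height"] * value / vmax


def _box_svg(stats: BoxplotStats, x: float, label: str) -> list[str]:
    g = _SVG_PLOT
    y = svg_value_to_y
    w = g["box_w"]
    cxm = x + w / 2
    parts = [
        f'<line class="whisker" x1="{cxm:.3f}" y1="{y(stats.minimum):.3f}" '
        f'x2="{cxm:.3f}" y2="{y(stats.q1):.3f}" stroke="black"/>',
        f'<line class="whisker" x1="{cxm:.3f}" y1="{y(stats.q3):.3f}" '
        f'x2="{cxm:.3f}" y2="{y(stats.maximum):.3f}" stroke="black"/>',
        f'<rect class="box" x="{x:.3f}" y="{y(stats.q3):.3f}" width="{w:.3f}" '
        f'height="{(y(stats.q1) - y(stats.q3)):.3f}" fill="none" stroke="black"/>',
        f'<line class="median" x1="{x:.3f}" y1="{y(stats.median):.3f}" '
        f'x2="{x + w:.3f}" y2="{y(stats.median):.3f}" stroke="black"/>',
        f'<text x="{cxm:.3f}" y="{g["y0"] + 16:.3f}" text-anchor="middle" '
        f'font-size="10">{label}</text>',
    ]
    return parts


def _render_svg(report: ComparisonReport, path: Path) -> None:
    g = _SVG_PLOT
    body: list[str] = []
    pairs = [
        ("control-X", report.control_x),
        ("predicted-X", report.predicted_x),
        ("control-Y", report.control_y),
        ("predicted-Y", report.predicted_y),
    ]
    for i, (label, stats) in enumerate(pairs):
        body.extend(_box_svg(stats, g["x0"] + i * g["gap"], label))
    svg = (
        '<svg xmlns="http://www.w3.org/2000/svg" width="340" height="300" '
        'viewBox="0 0 340 300">\n' + "\n".join(body) + "\n</svg>\n"
    )
    path.write_text(svg, encoding="utf-8")


def _render_png(report: ComparisonReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, (c, p, axis) in zip(
        axes,
        [
            (report.control_x, report.predicted_x, "X"),
            (report.control_y, report.predicted_y, "Y"),
        ],
    ):
        boxes = []
        for stats in (c, p):
            boxes.append(
                {
                    "whislo": stats.minimum,
                    "q1": stats.q1,
                    "med": stats.median,
                    "q3": stats.q3,
                    "whishi": stats.maximum,
                    "fliers": [],
                }
            )
        ax.bxp(boxes, showfliers=False)
        ax.set_xticklabels(["control", "predicted"])
        ax.set_title(f"coordinate-{axis}")
        ax.set_ylabel("pixels")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
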
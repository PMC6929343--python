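# Methods

This note documents the models, algorithms and design choices behind
`anchor3d`, in the order the pipeline runs them.

## Problem setting

Monogeneans are parasitic flatworms whose sclerotized haptoral hard parts —
in particular the anchors — are the characters taxonomists use to tell
species apart. Building a 3D model of an anchor by hand in a general-purpose
modelling package is slow and must be repeated for every new target shape.
`anchor3d` automates the process: a regressor locates the 34 landmark points
that define an anchor outline on a standardized 2D illustration, and those
landmarks drive the deformation of a single generic 3D anchor mesh into the
target shape. Training data are synthesized by shape-interpolation
augmentation, so the pipeline is self-contained and reproducible.

## Parametric anchor outlines (`anchor_shapes`)

An anchor outline is a closed polygon through 34 ordered point primitives on
a 96×96 pixel canvas (origin top-left, x right, y down, counter-clockwise as
seen on screen). The index ranges are fixed so corresponding indices are
anatomically corresponding across every shape the pipeline touches — the
interpolation, the regression targets, and the mesh controls all rely on
this correspondence:

| indices | region |
|---|---|
| 0–9 | base, traced across the two root lobes |
| 10–21 | outer side of the curved shaft (fan-like extrusion bulge, if any) |
| 22–33 | recurved point: outer approach, tip, inner return (hook, if any) |

Outlines are generated by sweeping a spine whose heading turns by
`shaft_curvature` degrees over the shaft and a further `point_recurve_angle`
degrees over the distal 40% of its length, with a half-width profile that
tapers from `base_width/2` to zero at the tip. Eight parameter presets define
the shape categories; categories 5 and 7 carry a fan-like extrusion on the
outer shaft and category 8 a hook near the tip — deliberately reproducing the
feature classes that are hardest for landmark-driven deformation (small
structures controlled by few primitives). Presets are structural stand-ins,
not taxonomically accurate reconstructions of particular species.

`generate_exemplar(category, seed)` jitters the preset parameters by ±5%
under the seed, giving distinct same-category individuals while remaining
bit-deterministic per `(category, seed)`. `perturb_exemplar` displaces every
point by a smooth random field: i.i.d. Gaussian draws per point are
circularly smoothed along the contour (Gaussian kernel, σ = 1.5 points,
window 7) and rescaled so the largest displacement equals the requested
magnitude. Smoothing is what keeps perturbed contours simple; independent
jitter self-intersects readily. Validation (`validate_outline`) checks point
count, canvas bounds, polygon simplicity (shapely, with an O(n²)
crossing-pair scan only to name the offending edges), positive area and
orientation; violations are returned as data, not raised.

## Augmentation (`augmentation`)

One morph batch interpolates a source exemplar toward a smoothly perturbed
target of the same category (default amplitude 4 px — large enough to change
the silhouette visibly, small enough that every intermediate stays a simple
polygon). The schedule captures 24 frames at `t_i = i/25`, strictly between
the endpoints. Each frame is independently rotated (uniform [0°, 360°)) and
isotropically scaled (uniform [0.6, 1.0] relative to the largest scale that
keeps the shape inside the canvas minus a 3 px margin) about its centroid —
per frame, not per sequence, which maximizes pose diversity in the training
set. Categories are assigned round-robin per record, so any requested total
is class-balanced to within one record.

Rasterization smooths the 34-gon with a closed uniform Catmull–Rom spline
(8 samples per segment; the spline interpolates its control points), fills it
dark-on-light at 4× supersampling with Pillow's scanline fill, box-downsamples
to 96×96, and flattens row-major to 9216 integers in [0, 255]. A square-area
oracle puts the fill accuracy at 0.2508 measured vs 0.25 analytic. Pixels
and landmark annotations are derived from the same transformed outline, so
re-rasterizing stored coordinates reproduces stored pixels bit-exactly — the
invariant the datastore and training stages rely on.

What the generator does *not* emulate: scan noise, stroke-width variation,
partial occlusion by other haptoral structures, and off-lateral poses. A
model trained on these synthetics therefore demonstrates the pipeline
mechanics, not robustness to wild images.

## Datastore (`datastore`)

Documents carry exactly the keys `_id` (auto-increment integer), `name`,
`shape`, `pixels`, `landmark{coordinate_X, coordinate_Y}` and serialize as
JSON Lines, one document per line. `export_matrices` flattens the collection
to `X (n×9216)` and `Y (n×68)` with interleaved coordinates
(x₀,y₀,…,x₃₃,y₃₃) in insertion order; the interleaving is a fixed contract
because the network's output layer depends on it.

## Landmark regressor (`landmark_net`)

Architecture: 9216 → 512 → 128 → 68, ReLU hidden activations, identity
output. Inputs are pixel intensities divided by 255; targets are pixel
coordinates divided by 96, keeping the MSE loss on the scale where a
learning rate of 0.01 is stable. Weights initialize from a zero-mean normal
with σ = 1/√fan_in, biases at zero, under the run seed.

Training: mini-batch SGD, batch 20, 200 epochs, learning rate 0.01, momentum
0.9, Nesterov formulation `v ← μv − ηg; θ ← θ + μv − ηg`, no decay, no early
stopping, batches reshuffled each epoch under the run seed. Splits: 20% of
all records (rounded) are the test set, 30% of the remainder the validation
set (5000 → 2800/1200/1000). The parameter update is implemented as a fused
single-pass numba kernel (bit-equivalent to the numpy formula, which remains
as a fallback); model arithmetic is float32 for training throughput and
float64 in the gradient-check tests, where analytic gradients match central
finite differences to ≤1e-5 relative error.

Accuracy metric: the within-tolerance hit rate — the fraction of
(record, landmark) pairs whose prediction lies within 3 px Euclidean
distance of the annotation. A distance-threshold hit rate is the standard
landmark-detection metric; it yields percentages comparable in spirit to a
regression "accuracy" without requiring one.

## Generic mesh and deformation (`mesh3d`)

The generic anchor model is built from an outline's spline contour: the
interior is triangulated (boundary sampled at 272 points, interior points on
a 2 px grid, Delaunay filtered to the polygon, chord edges between boundary
vertices midpoint-split so the glued result is manifold), then two mirrored
sheets with profile `z = ±thickness·√(d/d_max)` (d = distance to the
contour, thickness default 6 px) are glued along the shared z = 0 ring. The
34 control primitives are exact boundary vertices. The result is watertight
with Euler characteristic 2 for all eight category exemplars.

Binding uses mean value coordinates (Hormann–Floater formulation): every
vertex carries 34 weights over the control polygon; on-vertex and on-edge
queries take the indicator/linear special cases; the signed extension is
used for the few contour vertices where the Catmull–Rom spline bulges
outside the control polygon. Linear precision makes identity, translation
and uniform-scale deformations exact to ~1e-9, which the property tests
assert. Deformation moves each vertex's (x, y) to its weighted combination
of the predicted landmarks, leaves z untouched (so extreme scale changes
will look too thick or too thin — a known limitation), and refuses
self-intersecting landmark polygons rather than producing silently distorted
solids. The generic model is the category-1 exemplar (the plainest anchor:
no extrusion, no hook), so deformation onto categories with extrusions or
hooks exercises exactly the small-feature regime where distortion is
expected to concentrate.

## Evaluation (`evaluation`)

For each target illustration, the x and y coordinates of the annotated
control points and of the predicted landmarks are summarized by five-number
summaries (quartiles by linear interpolation of order statistics at
`1 + (n−1)p`; any consistent rule shifts Q1/Q3 slightly, so the rule is
fixed and oracle-tested). The report carries the per-statistic absolute
differences plus index-wise mean/max Euclidean error and RMSE — RMSE assumes
the control points are annotated in primitive order, and the report is
labelled accordingly. Boxplots render to PNG (matplotlib) or to a small
deterministic SVG whose box extents are written in a recoverable linear
data-to-pixel mapping, which the tests parse back.

## Pipeline and seeds (`pipeline_cli`)

The `anchor3d` CLI chains fixtures → augment → train → predict → deform →
evaluate. A single global seed is fanned out per stage via SHA-256 of
`"{seed}:{tag}:{stage}"` (truncated below 2³¹), so each stage is
independently reproducible; every run writes a manifest with the config
echo, derived seeds and SHA-256 checksums of all artifacts. Two runs with
the same config produce byte-identical predictions and meshes.

## Problem sizes used in the automated checks

The test suite trains the full-size network on synthetic datasets of 1000,
2500 and 5000 records for the dataset-size comparisons, and on reduced
datasets (a few hundred records, reduced epochs) for the pipeline smoke
tests. The acceptance script runs the end-to-end pipeline with the
5000-record model — the size the final pipeline adopts for landmark
prediction. All sizes are stated in the scripts themselves.

## Known limitations

- Landmark accuracy under full 360° pose variation is limited by the MLP
  architecture; see the dataset-size experiments for measured hit rates.
- Thickness is not rescaled during deformation.
- Index-wise evaluation presumes order-corresponding control annotations.
- The synthetic generator's realism gap (noise, stroke width, pose) means
  results bound pipeline behaviour on synthetics, not on scanned plates.
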
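# Methods

This note documents the model behind `leafsurf`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not demonstrate.

## Model and assumptions

A leaf surface is treated as a *developable-by-strips* object: a flat
2D shape (what you would get pressing the leaf in a book) deformed by
two low-order distortion modes constrained by the venation —
**bending**, a quadratic curve along the primary vein, and **rolling**,
a cubic curve across the leaf along secondary veins. The assumptions
this encodes:

* one primary vein, leaf longer than wide (checked: a first-to-second
  eigenvalue ratio below 1.2 emits a warning);
* the leaf would flatten without tearing or stretching (piecewise
  isometries model the deformation);
* distortion is no more complex than the fitted polynomials — a leaf
  that curls in two directions along the vein is outside the model;
* the cloud is a single segmented leaf in mm with world z up, and the
  world origin is the plant's emergence point (used only to orient the
  vein axis base-to-apex).

Because each reconstruction step is a rigid rotation of a point subset,
noise is never amplified and missing regions degrade the result only
locally — the property that motivates the shape/distortion split.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `grid_m` | 100 | side-view occupancy grid is m×m; finer grids barely change the normal search |
| `theta_step_deg` | 1° | sweep resolution for the normal; bounds the axis error |
| `skeleton_n` | 50 | skeleton samples; N−1 strips partition the leaf |
| `delta` | 5 | strips with fewer points are skipped (a cubic needs 4 points; 5 adds slack) |
| `degree_bending` / `degree_rolling` | 2 / 3 | polynomial orders of the two skeleton fits |
| `degree_alignment` | 3 | wl-midline fit used to re-align strips (order unconstrained by the method; cubic matches rolling) |
| `expand_frac_bending` | 0.05 | bending sampling interval widened so strongly curled tips stay inside the strip range |
| `outlier_k`, `outlier_std_mult` | 50, 1.0 | mean-kNN-distance outlier filter (preprocessing only) |

All lengths are mm; areas are reported in cm² at the interface and kept
in mm² internally.

## Numerical and interpretation choices

* **Normal-axis seed and grid.** The perpendicular seed axis for the
  θ-sweep is deterministic (`l × e_min`, with `e_min` the world basis
  vector least aligned with l): any seed is valid since the full half
  turn is searched, and determinism makes runs reproducible. The grid
  extent along the rotating axis is the maximum radial distance from
  the l-axis, fixed once, so every rotated projection stays in-bounds.
  Ties in S(θ) break to the smallest θ.
* **Eigenvector signs** are normalized (largest-magnitude component
  positive) before the base-to-apex flip, removing solver dependence.
* **Frame handedness.** The leaf frame is defined by w = l × h, which
  together with "h up" yields an improper (mirror) basis; all
  quantities used downstream (|h|, w-extents, areas, chord lengths)
  are invariant to this, and a leaf posed upside-down flips (w, h)
  jointly — the only frame ambiguity.
* **5% bending expansion** is split symmetrically (2.5% per end): which
  end holds the curled tip is unknown a priori, and the symmetric split
  never guesses wrong by more than the one-sided variant.
* **Skeleton sampling beyond the data range** (from the expansion) is
  evaluated through the fitted polynomial — extrapolation is exactly
  what lets curled tips unroll.
* **Point-to-strip assignment** is a single pass over segments in
  increasing order; each point is harvested by the first segment whose
  flattened interval contains its transformed a-coordinate, then
  leaves consideration. One rigid map per point means no
  double-counting of area. Points that no interval captures are
  dropped and counted (the expansion keeps this rare); the last
  interval is closed so the extreme point survives.
* **Landmark lift.** Strip re-alignment needs a 3D distance between a
  strip-skeleton point (w, h) and a midline point (l, w). The strip
  point receives l = the midpoint of the strip's flattened l-interval;
  the midline point receives h = 0. This uses only quantities the
  algorithm already has; ties break to the lower index.
* **OLS fits** go through numpy's SVD-based polynomial least squares;
  no regularization.
* **Degenerate inputs** raise typed errors: collinear clouds and
  zero-a-spread projections (no polynomial exists), centroid at the
  origin (vein orientation undefined), coincident skeleton points,
  polygons with zero area. Sparse strips raise a skip signal that the
  pipeline logs and tolerates; a leaf whose every strip is skipped is
  an error.
* **Statistics conventions.** Distortion uses the population std (the
  cloud is the whole population of interest); series statistics use
  the sample std. Consecutive-frame differences are absolute values —
  the target is jump magnitude, and the statistic is then symmetric
  under time reversal.

## The synthetic generator

The generator exists so that every pipeline stage has an oracle. A flat
ovate outline (half-width `(W/2)·sin(π l/L)^p`) is sampled uniformly
(binomially thinned from the bounding box, so counts track
density × area), then distorted by the **exact inverse** of the
flattening operator: curve nodes with equal chord lengths are placed on
the target bend/roll polynomials and each strip is rigidly rotated onto
its segment. Because this is a piecewise isometry, the distorted leaf's
flattenable area equals the analytic outline area — naive
h-displacement would stretch the surface and make "true area"
ill-defined. Node chains are anchored at the quadratic's apex (and at
w = 0 for the roll cubic) so a symmetric sag produces a symmetric leaf
whose mean orientation coincides with the declared true axes; a fold
guard rejects curves whose turning radius drops below the cross-
section height. Gaussian jitter models sensor noise, spherical
deletions model occlusion holes, and a uniform random rotation about
the leaf base (resampled until the normal is at least ~8.6° off
horizontal, since a top-down scanner never sees a perfectly vertical
leaf and the "normal points up" rule would be undefined) models pose.

Two presets set the species contrast used in benchmarks:
`sugarbeet` (120×50 mm, sag 30 mm, roll 9 mm — strong distortion) and
`soybean` (70×45 mm, sag 8 mm, roll 3 mm — mild), both with 0.3 mm
noise and small occlusion holes, 2 points/mm².

What the generator does **not** emulate: anisotropic scanner noise and
specular dropouts, self-occlusion geometry (holes are spheres),
serrated or lobed outlines, petioles, and within-leaf growth
heterogeneity. Passing the synthetic benchmarks therefore demonstrates
correctness of the geometry pipeline and robustness to generic noise
and missing data, not performance on every real canopy.

## Benchmark problem sizes

The bundled checks run on desk-scale problems chosen to exercise every
code path at comfortable statistical margins: area recovery on a
100×40 mm leaf at 5 points/mm² (~12 700 points), distortion reduction
on 20 preset leaves, axis recovery over 100 random poses, 10⁴ random
skeleton polylines for the isometry bounds, and two 50-frame growth
series (truth grows exactly linearly, so the fit R² isolates
reconstruction jitter). Typical results: area within ~2% (noiseless)
and ~3–5% (0.5 mm noise plus two 5 mm holes), residual distortion
below 1% of the input on noiseless leaves, axis errors below ~2.5°,
and series R² above 0.99.

## Known limitations

* Leaves whose distortion exceeds the polynomial orders (double curls,
  dragon-curve edges) are underestimated — the strip rectangles then
  clip real surface.
* Very sparse clouds lose strips to the δ rule; gaps are left, not
  interpolated.
* The strip-rectangle area slightly overestimates tapered outlines
  (each rectangle spans the strip's full w-extent); the bias shrinks
  as 1/N and is under 1% at N = 50 for a triangular taper.
* Alignment can fail gracefully (skipped strips) when a strip's
  cross-section fit is poor; consecutive-strip information is not yet
  shared.
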
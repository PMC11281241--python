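# Methods

This note documents the models, numerical choices and limitations behind
`podsplit3d`.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Triangulation model

A pixel `(u, v)` (0-based, `(column, row)`, pixel centres at integer
coordinates) defines the viewing ray
`(Xc, Yc, Zc) = Zc · ((u−u0)/fx, (v−v0)/fy, 1)`.  Substituting into the
light-plane equation `a·Xc + b·Yc + c·Zc + d = 0` gives the closed form

    Zc = −d / (a(u−u0)/fx + b(v−v0)/fy + c)

A denominator below 1e−12 (ray parallel to the sheet) is an error.  The
depth sign follows the supplied plane coefficients; with the published rig
parameters the principal-ray depth is negative (≈ −532.8 mm), which the
implementation accepts — no camera-axis sign convention is imposed.

The world transform is the exact closed-form inverse
`world = Rᵀ(camera − T)`.  Supplied rotation matrices are validated against
`RᵀR = I` and `det R = 1` at 1e−6 but only *warn* when violated, because
published calibrations are commonly orthonormal to only ~1e−3; in that case
`Rᵀ` and the true inverse differ by the calibration's own residual (the
tests bound this at 0.1 mm for the published values).

Splicing adds `d = v·t` along a configurable guide axis (default world +Y)
*after* the world transform.

**Stripe centreline.**  Per image column, the intensity-weighted centroid
of pixels above a threshold.  For an untruncated discrete Gaussian profile
the centroid equals the true centre to machine precision (the aliasing
error of Gaussian-windowed sampling is `O(exp(−2π²σ²))`, i.e. ~1e−35 at
σ = 1.5 px), which is why noise-free synthetic scans reconstruct a flat
table to better than 1e−6 mm.  With 8-bit frames or added noise the
accuracy is set by quantisation/noise, not by the extractor.

## Surface features and region growing

Normals/curvature come from the covariance of each point's k-neighbourhood
(the point plus its k nearest neighbours; KD-tree, ties broken toward the
lower point index).  The normal is the eigenvector of the smallest
eigenvalue; the surface-variation curvature `ρ = λ₁/(λ₁+λ₂+λ₃)` lies in
[0, 1/3] by construction.  Normals are sign-disambiguated toward a
viewpoint (+Z at infinity by default — the camera hangs above the table).

Region growing is deterministic: global seeds in `(curvature, index)`
order, FIFO growth, and the two-tier rule — a neighbour whose (unoriented,
`|n₁·n₂|`) normal angle to the **current seed** is below `angle_thresh`
joins the region; it is promoted to a seed only if its curvature is below
`curv_thresh`.  Undersized regions dissolve into the residual (label −1)
and growing stops when fewer than `min_region` points remain.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `k` | 30 | ~1 mm neighbourhoods at the scan densities used here; stable PCA without washing out the waist |
| `angle_thresh` | 15° | ≥ 4× the per-step normal change on a smooth pod at 0.35 mm spacing, ≪ the crease flip between touching pods |
| `curv_thresh` | 0.08 | must separate two regimes measured on scanned clouds: smooth pod features including the wasp waist saddle reach ρ ≈ 0.06–0.075, while pod–pod adhesion creases exceed ρ ≈ 0.1.  0.05 splits wasp-waist pods at their own waist; 0.08 does not, and still never promotes crease points |
| `min_region` | 100 | well below any single-pod point count at the default scan density, well above stray clusters |

The elevation pre-filter removes the table band before features are
computed.

## Rolling-ball boundary

`(A, B)` with `|AB| ≤ 2r` is a boundary edge iff one of the two radius-`r`
disks through `A` and `B` (centres `C ± D·H`, `D = sqrt(max(0, r² −
(L/2)²))`, so the tangent case `|AB| = 2r` needs no special-casing)
contains no other point strictly inside, where "strictly" means distance
`< r − 1e−9·r` — points exactly on the circle never block an edge.
Candidate blockers come from a KD-tree ball query around each centre,
which is exactly equivalent to the naive all-points scan (anything inside a
circle is within `r` of its centre); the tests assert edge-set equality
with an exhaustive O(M³) enumeration.

The contour is ordered by a greedy walk (smallest turning angle at
branches, largest-area closed loop kept) and normalised counter-clockwise.
Rasterisation draws Bresenham segments on a grid with an exact affine
pixel↔mm map (`mm = origin + pixel · mm_per_pixel`); under this convention
a closed 10 mm square at 1 mm/px spans 11 pixel centres, not 10.  The
default ball radius is 3× the median nearest-neighbour spacing of the
projected points.

In the pipeline the ordered polygon is offset outward by half the point
spacing before rasterisation: boundary *samples* sit, on average, half a
spacing inside the true silhouette, and without the offset the discrete
scale search systematically prefers a shrunken template.

## Shape-based matching

The template preprocessing chain is threshold → morphological closing →
8-connected components → hole fill → area window (exactly one surviving
component required) → outer contour.  Contour tangents are taken on a
lightly smoothed curve (5-tap moving average, ±3 central difference)
because marching-squares vertices stair-step at pixel scale; normals point
outward.  Levels halve both resolution and point count; every level keeps
≥ 8 points.

Similarity of a pose is the mean over model points of the absolute cosine
between the transformed model normal and the unit image gradient (zeroed
below 10 % of the maximum gradient magnitude) — bounded in [0, 1], tolerant
to contrast polarity.  The coarse level is searched exhaustively over
translations × angles × scales; at each translation peak *all* angles
within 0.08 of the local best are spawned as candidates, because
near-symmetric contours tie across rotations (including the 180° flip) at
coarse resolution and only finer levels can discriminate.  Candidates are
tracked down with ±2 px, ±1 (halving) angle step, ±1 scale step windows.

Refinement iterates a 3-unknown linear least squares on the
point-to-tangent residual `(W·pᵢ − sᵢ)·nᵢ` with the small-angle `W`
(correspondences: nearest edge point within 5 px; Canny edges with Sobel
gradient normals).  A backtracking step (halving up to 3×) keeps the mean
absolute residual non-increasing; iteration stops at |update| < 1e−3.
Scale is held fixed during refinement — the rigid model has no scale
parameter; scale is resolved by the discrete sweep.

Masks are the filled transformed contour, repaired by a morphological
opening with a disk element (anti-extensive and idempotent; note a disk
rounds the few unreachable pixels at perfectly sharp convex corners —
visible on synthetic squares, irrelevant on smooth pod contours).

## Synthetic scenes

**What is emulated.**  Pods are height fields over a table: a two-lobed
profile (circles `r1`, `r2` with centres `separation` apart, joined by a
C¹ smooth maximum with the constant baseline subtracted so the profile is
exactly zero outside both lobes), low-pass filtered along the axis
(Gaussian, σ = 0.8 mm — real pod necks are smooth, whereas raw circle
unions have a V-kink where the circles cross), then pinched by a Gaussian
waist calibrated so that mid-girth / max-girth equals the `waist` factor
exactly.  A sinusoidal bump texture (default 0.08 mm) modulates the radial
profile with a one-step azimuth estimate, keeping the surface an explicit
height field.  Pods rest on their widest girth with yaw-only pose; scene
presets chain pods tip-to-tip with 0.15 mm clearance between measured
silhouettes — below the rendering pixel — so rendered blobs merge while
the convex solids never interpenetrate (a tolerance check enforces this).

The scan simulator intersects the laser sheet with the height field by
bracketing + bisection (topmost root = nearest the camera), adaptively
subdividing steep segments so only genuine silhouette discontinuities are
skipped, projects exactly through the pinhole model, and renders one
untruncated Gaussian stripe centre per integer column.  `noise_px` jitters
the stripe centre per column.  The top-down renderer shades by surface
height with additive Gaussian noise; truth masks come from the same
geometry (ties to the taller pod) and are therefore exact.

**What is not emulated** — and hence what passing tests do not show about
real data: laser speckle and stripe width variation, lens distortion,
specular highlights and shadows on the shell, partial transparency,
non-resting poses (tipped or stacked pods), deformed or broken pods, and
mutual *laser* occlusion (the simulator keeps the topmost surface point
per column; the reported occlusion failure mode of tall neighbours is
reproduced only through camera-side geometry).

**Problem sizes.**  Default study conditions: 0.35 mm stripe spacing
(≈ 60–130 frames/scene), 800×700 px virtual sensor 300 mm above the table
(focal 900 px, sheet tilt 25°), 0.25 mm/px top-down renders, two- to
four-pod scenes.  These sizes keep a full five-scene evaluation around a
minute while leaving every stage's error an order of magnitude inside its
tolerance; all are parameters, not constants.

## Evaluation

`P = 100·K₁/K₂` per object and the pixel-weighted
`σ = 100·Σzᵢ/ΣZᵢ` (ratio of sums, not mean of ratios; `σ = P` at m = 1).
Predictions are assigned to truth objects by Hungarian matching on IoU.
By default `K₁` counts *intersection* pixels so over-segmentation cannot
inflate the score; the raw predicted-count mode (used when no truth masks
exist) is retained and flags values above 100 % with a warning.

## Known limitations

- The rolling-ball edge test is O(pairs × ball query); for very dense
  projections subsample first (the pipeline caps at 1800 points).
- Region-growing thresholds are scale-dependent: `curv_thresh` was chosen
  for ~0.3–0.5 mm point spacings; much denser or sparser clouds shift the
  curvature regimes and need re-inspection.
- The matcher assumes the target appears at near-identical scale (±10 %)
  and arbitrary rotation; strong perspective or tilt is out of scope.
- `label_points` assigns cloud points to pods through the height-field
  column model; points far from any surface (heavy noise) fall back to
  "unassigned" rather than a nearest-surface guess.
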
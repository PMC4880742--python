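# Methods

`carbplate` estimates the carbohydrate content of a plated meal from two
photographs taken at prescribed angles (one near-vertical, one tilted by
~15° from the vertical axis through the plate center) with a planar
reference card of known physical size beside the plate. This note
documents the models and procedures behind each stage, the parameters
that matter, what the synthetic scene generator does and does not
emulate, and the numerical choices and limitations a user should know
about.

## Geometry and conventions

World frame: the table plane is `z = 0` (cm), the plate center is the
origin, `z` points up. The camera is an ideal pinhole with square
pixels (no lens distortion — a device property, not part of the method);
its tilt rotates the viewpoint about an axis through the plate center,
matching the capture protocol. Pixel coordinates are 0-based
`(row, col)` with sub-pixel positions as floats. Volumes are in ml
(1 ml = 1 cm³), masses in grams.

Capture validation accepts a view iff its tilt is within ±3° of the
target (0° and 15°), mirroring the protocol's on-screen angle gate.

## Plate detection

The dish is assumed round, so its image is an ellipse. Edges come from
a Canny detector (σ = 2, absolute thresholds 0.10/0.20 on unit-range
gray), tuned so that texture gradients inside surfaces stay below
threshold while object boundaries pass. The ellipse is found by RANSAC
over 5-point minimal conic fits with a first-order (Sampson) geometric
distance and a 2 px inlier tolerance, followed by direct least-squares
ellipse refinement (Fitzgibbon, stable split-design variant) on the
inliers, twice. Two details matter in practice:

* **Chain-guided sampling.** Edge pixels of one physical boundary form
  connected chains; half the RANSAC samples draw all five points from a
  single 8-connected chain (chains weighted by size). This finds the
  rim orders of magnitude faster than blind sampling when the scene has
  thousands of texture/card/item edge pixels.
* **Tie-breaking.** Among candidate ellipses, the largest inlier count
  wins; ties break toward larger area (the plate dominates the scene).
  Degenerate minimal-sample conics (hyperbolas/parabolas) are discarded.

Iteration count adapts with the standard (1−w⁵) confidence formula,
capped at 600; the fit is invariant to point order and duplication
because points are deduplicated and canonically ordered before sampling.

## Segmentation (grow, merge, exclude)

Color distances are Euclidean in CIELAB computed on a lightly smoothed
image (Gaussian σ = 1.2) so pixel noise and fine texture do not
fragment regions. Automatic mode seeds a regular grid (spacing 1/12 of
the plate major axis, clipped to the ellipse); interactive mode uses one
user seed per item. Growth is best-first accretion of 4-connected
pixels: the candidate with the smallest ΔE to its region's running mean
expands first, a pixel is claimed at most once, growth stops at
ΔE > `grow_tol` (default 16). Ties break on (distance, pixel index,
region id), making the result deterministic.

Growth leaves a thin unclaimed halo of color-mixture pixels at
boundaries; a completion pass assigns leftover plate-interior pixels to
the closest frozen region mean (the plate background competes with its
own mean color), placing the boundary at the color midpoint, with a
connectivity filter reverting detached assignments. Adjacent regions
are then merged by cost `ΔE / (1 + β·min(border_fraction, 0.5))`
(β = 1): merging continues while the best cost is below
`merge_cost_max` (12), while the region count exceeds `max_regions`
(6), or while a region is smaller than `min_region_area_frac` (2.5% of
the plate-ellipse area; undersized isolated fragments dissolve into
background). Non-adjacent regions never merge. Regions whose mean
color matches the plate (ΔE < 8 to the largest region in automatic
mode, or to the unclaimed-pixel mean in seeded mode) are excluded, and a
final boundary-refinement pass re-decides a ±2 px band on the
*unsmoothed* image, removing the ~1 px silhouette bias the smoothing
introduces. Labels are relabeled consecutively by decreasing area.

The default thresholds were chosen from the measured CIELAB statistics
of the synthetic food classes (within-item 98th-percentile spread ≤ ~20,
item-to-plate and cross-item distances ≥ ~25) so that each clause has
headroom on both sides; on real photographs they are configuration.

## Recognition

Each region is described by a 4×4×4 joint RGB histogram (64 bins) plus
a uniform local-binary-pattern histogram (P = 8, R = 1; 10 bins) over
the region eroded by one pixel, both L1-normalized — 74 dimensions.
Erosion makes the texture block exactly translation invariant (every
LBP neighborhood lies inside the region). A constant region puts all
LBP mass in bin 8 (the all-ones uniform pattern: every neighbor ≥
center).

The classifier is an RBF one-vs-one SVM (C = 10, γ = "scale") with
Platt-style sigmoid calibration (`CalibratedClassifierCV`,
`ensemble=False`), producing a probability over the nine classes; the
ranked list is sorted by confidence with ties broken by class-list
order, and a manual override moves the chosen class to rank 1 with
confidence 1. Two deliberate choices:

* **No per-dimension standardization.** The features are sparse
  normalized histograms; standardizing near-constant bins inflates
  slightly out-of-distribution queries to enormous z-scores and
  saturates the RBF kernel (every kernel value ≈ 0, the intercept
  decides). Raw histograms with γ = "scale" behave correctly.
* **Canonical sample ordering before fitting** (by class, then
  lexicographically by features) makes training invariant to the order
  in which examples are supplied.

## Two-view reconstruction and volume

**Matching.** ORB keypoints (≤800/view) with cross-checked ratio-test
matching, then sub-pixel correction of each match by a local SSD
template search with parabola interpolation (ORB localizes to ~1 px;
the metric scale is computed from these points, so the fraction of a
pixel matters). A dominant-plane prefilter (coarse homography RANSAC,
generous 12 px gate) removes the gross one-texture-period-off mismatches
that periodic table patterns produce; genuine food parallax stays well
inside the gate.

**Pose.** A meal scene is quasi-planar — table, plate rim and card are
coplanar and food relief is a few percent of the camera distance — which
is a degenerate configuration for the linear 8-point essential-matrix
algorithm. The relative pose is therefore recovered from the
dominant-plane homography: RANSAC (4-point DLT, 2 px tolerance) followed
by refits at tightening tolerances (2 → 0.75 px, so off-plane food
points cannot contaminate the plane), then the SVD (Faugeras)
decomposition into (R, t̂, n) candidates. The two-fold ambiguity is
resolved by cheirality plus the epipolar (Sampson) support of *all*
matches — the off-plane food points break the tie.

**Dense depth.** The pair is rectified (rotating both cameras so the
new x-axis lies along the baseline), block-matched along scan lines
(5×5 SSD, disparity range taken from the sparse matches ±6 px,
left-right consistency within one step, parabola sub-pixel), and
triangulated. Model units set the baseline to 1; the reference card's
four triangulated side lengths against its physical size give the
model→cm factor (mean of the four ratios). Card corners are located
from the dark border frame: largest dark component outside the plate,
minimum rotated rectangle, then sub-pixel refinement by intersecting
total-least-squares line fits to the four outer contour edges (the
tilted view makes the card a trapezoid, which a bounding rectangle
mis-corners by a few px).

**Plate plane and integration.** A RANSAC plane (3-point samples,
tolerance 0.4% of median depth) through reconstructed points that fall
inside the plate ellipse but in no food region defines height zero; the
normal is oriented toward the camera so food heights are positive. Each
region's points are projected onto the plane and binned into a grid
(0.2 cm cells, widened to ≥1.25 pixel-footprints so cell statistics
stay dense); cell height is the mean point height (signed — negatives
average out — clipped at zero after averaging). The integration
*footprint* is obtained by ray-casting all region pixels (centers plus
quarter-offsets) onto the plane with fractional cell coverage, so the
area does not depend on which pixels survived the consistency check.
Because the matching window drags heights toward the plate near the
silhouette, heights are taken from interior cells (erosion adapted to
the window's physical width) and extended to the footprint rim —
silhouette sides are treated as vertical walls, which is exact for
boxes/cylinders and a small (+few %) overestimate for domes. Volume is
`Σ coverage · height · cell²`, in ml.

Measured accuracy at the default rendering scale (320² px, 45 cm):
spherical-cap and box primitives within ±7%, full-scene per-item volumes
typically within ±10%, height-noise floor ≈ 0.5 mm (so a flat 7 cm²
"sticker" reads ≈ 1 ml, not 0). Doubling every physical dimension
multiplies volumes by 8 within ~4%.

## Carbohydrates

Each class carries one carbohydrate density ρ in g/ml (the quantity
that multiplies a volume): nutrient databases list carbs per 100 g of
*mass*, so building a table requires a per-food served mass density;
the packaged `data/carb_density.csv` stores the pre-combined value with
a provenance note per row and is a synthetic toy table for testing, not
nutritional ground truth. Carbs are exactly `volume × ρ` per item and
additive across items; a manual class override changes the meal total by
exactly `(ρ_new − ρ_old) × volume`.

## Study statistics

Per-meal signed error is estimate − truth; percentage error is
|error|/truth × 100, averaged per meal (not as an aggregate ratio).
"Within the clinical band" is a strict |error| < 20 g (an error of 20 g
or more measurably affects post-meal glycemia — the design target).
Printed percentages round half away from zero to one decimal. The
with/without comparison uses an independent two-sample Mann-Whitney U
on absolute errors (U of the first group from midrank sums): exact p by
full enumeration of C(nA+nB, nA) labelings when nA+nB ≤ 12 with no
ties, else normal approximation with midrank-tie correction and
continuity correction (verified against an independent implementation).
The measurements are actually paired per meal; the independent test is
implemented deliberately as the evaluation machinery specifies and is
conservative here. Outlier participants are those with more than half
of their meals beyond the 95th percentile of all per-meal absolute self
errors — the signature of a consistent extreme over/under-estimator —
rather than a percentile rule on per-participant means, which would
flag the worst participant even in homogeneous data.

## Synthetic scene generator

Scenes are rendered by analytic ray casting of geometric primitives
(spherical caps, boxes, vertical cylinders) on a flat plate disc, with a
white/black-bordered reference card (default 8.5 × 5.4 cm, credit-card
format) on a textured table. Appearance is a per-class base color
modulated by a procedural texture evaluated at the *world-space* hit
point — so texture is consistent between views, a prerequisite for
stereo — plus mild Lambertian shading and per-view additive Gaussian
pixel noise (default σ = 2 gray levels). Classes share base colors in
pairs (pasta/potatoes, rice/mashed potatoes) so texture features carry
real discriminative weight, and randomized meals draw one item per food
group (carbohydrate, protein, vegetable), as plated meals do. Rendering
is pure: identical inputs give bit-identical images, and the seed drives
only the pixel noise. Item sizes give 30–400 ml per item.

What the generator does **not** emulate — and hence what passing tests
do not show about real photographs: mixed/occluded/sauce-covered foods,
specular highlights and shadows, lens distortion and rolling shutter,
irregular plate shapes, real food texture statistics, and hand-held
angle error (cameras sit exactly at the nominal tilts; the tolerance
gate is tested separately). The printed study percentages are
reproduced from their count pairs; the clinical error magnitudes of a
human study are not reproducible at desk scale.

Synthetic study tables emulate the evaluation design: participants each
estimate a block of six meals served in three sizes (multipliers
0.7/1.0/1.4 on a 20–80 g base); self-estimates get Gaussian error
(default SD 35 g, bias −5 g, reflecting the tendency to underestimate),
system estimates SD 12 g, both clamped at 0; an optional fraction of
participants are extreme over-estimators (+150 g on every meal).

## Benchmark sizes

The accuracy surfaces are computed at these problem sizes (chosen so the
whole suite re-runs comfortably on one CPU): plate detection on 100
scenes × 2 views (noise σ ∈ [0, 5]); automatic segmentation on 100
scenes (all items IoU ≥ 0.8); recognition trained on 20 and tested on
30 renders per class (270 held-out items); volumes on 3 seeds per
primitive plus one ×2-scaled pair; end-to-end carbohydrate error on 50
scenes against ground-truth volume through the same density table;
Mann-Whitney power over 200 replicated n = 114 studies.

## Known limitations

* Sparse-match precision is the weak link: ~15–25% of ORB matches sit
  1.5–12 px off (coarse-octave keypoints); robust pose estimation
  absorbs them, but the metric scale still varies by ±1–3%, i.e. ±3–9%
  on volumes.
* Heights come from the visible surface only; overhangs and concavities
  under the visible surface are invisible to any two-view method.
* The toy density table makes the carbohydrate outputs illustrative;
  real deployments must supply a table derived from a nutrient database.
* The interactive mode is exercised programmatically (seed lists); no UI
  is provided.
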
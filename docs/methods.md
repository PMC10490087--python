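# Methods

This note documents the models, parameter choices and known limitations of
the mealvision measurement chain, in the spirit of a statistical package's
methods appendix. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
measurements.

## The metric chain

A meal photograph carries no absolute scale. The system's single metric
anchor is a flat reference card of known physical size (default 85.6 ×
54.0 mm, the ID-1 credit-card format; both dimensions are configuration)
lying on the table beside the food.

**Card pose.** Detection reduces the card's bright region to a
quadrilateral (convex hull, best four-vertex subset by area; candidates
ranked by rectangularity × area). Because thresholded pixel centres sit
strictly inside the card, the quad is dilated outward by half a pixel,
which removes the systematic half-pixel-per-side shrink; the residual
edge-phase error is zero-mean. The planar pose comes from decomposing the
metric-rectangle-to-image homography with the intrinsics (H ≈ K[r₁ r₂ t]),
taking the solution with the card in front of the camera and the normal
facing it. Corner ordering is canonical clockwise from a long edge; the
remaining two-fold ambiguity is harmless for a plain rectangle, and all
pose consumers (alignment, baseline recovery) use only ordering-invariant
quantities (plane, centre).

**Alignment.** Depth providers may be metric only up to scale. The map is
rescaled so the median depth over the card region equals the card
*centre's depth along the optical axis* (the camera-frame z of the pose
translation). The Euclidean camera-to-card distance is deliberately not
used: for a card placed off the principal axis — the normal case — it
exceeds the axial depth by several percent and would inflate the scale of
an already-metric map. The median (not mean) resists speckle outliers.
The operation is idempotent: re-aligning aligned depth gives scale 1.

**Plane refinement.** Four projected corners of an ~85 px card constrain
the plane normal only through sub-pixel foreshortening, so the
homography normal can be off by a few degrees — enough to tilt the height
field and bias volumes by >10% at oblique views. After alignment the
card plane is therefore re-fit by least squares to the back-projected
depth points under the detected card region (or, in the stereo path, to
the triangulated card-region points). The homography pose still supplies
the scale; the fit supplies the plane.

## Volume estimation

A single downward view observes only each item's top surface, so the
faithful volume model is a 2.5-D height field over the card plane, not a
closed surface: masked depth pixels are back-projected, moved to the card
frame (card plane z = 0, +z toward the camera), cleaned, and integrated
as `Σ cell_area × median(z per cell)` over a 2 mm plan-view grid. Empty
cells contribute nothing — no inpainting — so the estimator is easy to
reason about and strictly local. The 2 mm cell is a compromise: fine
enough that edge cells are <2% of typical item areas, coarse enough that
most cells hold several points for a stable median.

Cleaning applies, in order:

* **Statistical outlier removal** (k = 20 neighbours, threshold mean +
  2 sd of the mean-kNN-distance statistic) — common point-cloud defaults.
  On a hard-edged clean grid this statistic flags the outer one or two
  rings of points (a perimeter effect, ~4/√N of the cloud, interior
  untouched); that is accepted as the cost of reliably catching genuine
  speckle.
* **Height plausibility rules**: the bottom of an item may sit at most
  5 mm below the card plane, and nothing rises more than 5 cm above it.
  Points outside the band are discarded; surviving heights clip into
  [0, 50] mm. A 0.5 mm guard band at the top cutoff keeps surfaces
  legitimately *at* the 50 mm limit from vanishing under sub-percent
  metric-scale error (they are clipped to 50 mm, so nothing outside the
  band ever contributes volume). Whether the original rules clip,
  translate or discard at the lower boundary is underdetermined;
  discard-then-clip-at-plane is this package's reading.
* **Plausibility cap**: no single item exceeds 2.5 cups. The cup is fixed
  at the 240 mL nutrition-label cup (cap 600 mL), exposed in
  configuration; the cap applies last, after all cleaning.

If the card is missing or any stage leaves too little geometry, the item
falls back to its standard serving volume from the nutrient table —
degradation, never an exception.

## Stereo back-end

The two-view variant (default elevations 90° and 75° on a vertical arc
through the scene centre, preserving distance) estimates the fundamental
matrix from exact correspondences (card corners plus food-surface
keypoints; ≥8, non-coplanar) with the normalised 8-point algorithm,
upgrades it to an essential matrix with the intrinsics, decomposes to a
relative pose with a cheirality check, and builds calibrated row-aligning
rectifying homographies from the rotations. Calibrated (rather than
purely projective) rectification is used so that disparity converts to
depth by the exact closed form `Z = f·B/d`. Matching is SAD block
matching (block 11 px) with a uniqueness margin of 5% of the block cost
scaled by image contrast — pixels whose best and second-best costs
(excluding neighbouring disparities) are too close, or whose alternatives
could not be evaluated, are invalid; perfectly uniform images are wholly
invalid. Integer disparities are the reference behaviour; a parabola
sub-pixel refinement is an optional flag (the high-level pipeline enables
it). The search is windowed to the disparity range and image region the
scene geometry can produce, which cuts the cost volume by an order of
magnitude without changing any result inside the window.

The phone's true baseline is unknown, so it is recovered from the card:
with the card centre at X_a and X_b in the two camera frames and relative
pose x_b = R x_a + s·t, the scale s is the projection of the residual
onto t. The centre (not the corners) is used so the result does not
depend on how each view's detector ordered the corners of a symmetric
rectangle.

## Nutrition

Nutrient tables are CSV keyed by fine category with density (g/mL), kcal
and macros per 100 g, and a standard serving volume (mL). Lookups try the
primary table, then the secondary, recording provenance — the fallback
*order* is the behaviour under test; live database access is out of
scope. The bundled 20-category table uses label-convention values; its
olive-oil entry (density 0.91 g/mL, 800 kcal/100 g, 90 g fat/100 g) makes
the canonical hidden-ingredient example reproduce exactly: 50 g → 400 kcal
and 45 g fat. Zero-energy drinks carry explicit records rather than being
skipped. Packaged products bypass volume: per-package nutrients × fraction
consumed, keyed by an EAN-13 barcode whose checksum is validated.

## Evaluation statistics

The unit of analysis is the participant-day (references cover whole days).
Per nutrient: APE = 100·|est − ref|/ref per participant; MAPE is the mean
with the sample (n−1) standard deviation; a single participant reports
sd = 0 with a warning rather than failing. Bland–Altman uses differences
est − ref with limits of agreement at mean ± 1.96 sd (the 95% convention).
Method comparison is Welch's unpaired t-test on the two APE lists —
pooled-variance and paired variants are plausible alternatives; Welch
unpaired is the package's choice, with the degenerate identical-constant
case reported as t = 0, p = 1.

## Synthetic data: what it does and does not emulate

The renderer produces a planar table, a zero-thickness card flush with the
plane, and parametric solids (cuboid, cylinder, spherical cap, conical
frustum) with closed-form volumes, under an exact pinhole ray-caster:
per-pixel depth is the true ray/solid intersection along the optical
axis, masks are nearest-hit, card corners are exact projections, and the
grayscale texture is a hash of the quantised 3-D surface point so both
stereo views see the same surface pattern (the photoconsistency block
matching needs). The default card centre avoids placing card edges
exactly on pixel centres of the reference cameras, where floating-point
ties make boundary pixels flicker.

Deliberately not modelled: lighting, shading, specularity, lens
distortion, rolling shutter, motion blur, partial pixel coverage
(anti-aliasing), occlusion between items beyond nearest-hit masks, and
non-rigid or mixed foods. Consequently, passing tests demonstrate the
geometry and statistics of the chain, not robustness to real-image
nuisances; segmentation and recognition are contracts filled by an
index-channel segmenter and an oracle classifier (true label at a
configurable rank), because trained networks are external to this
package.

Degradation is emulated by seeded Gaussian depth noise plus gross uniform
outliers replacing `round(frac·n_valid)` pixels, and the synthetic
feeding study draws meals from a scene catalogue, computes true daily
totals from closed-form volumes and the bundled table, and multiplies
truth by log-normal noise with mean 1 and coefficient of variation
`noise_cv` per nutrient and participant (recall error is proportional).
Days are redrawn around at least one energy-bearing meal so percentage
errors stay defined. CV 0.10 implies a mean APE near 8% when estimates
equal truth, which the 200-participant recovery check verifies against a
[7%, 13%] band.

## Numerical and testing choices

* Pixel (u, v) is the centre of its cell, 0-based; depth is distance
  along the optical axis. Volumes convert mm³ → mL by ÷1000.
* Closed-form solid volumes are verified against an independent voxel
  (midpoint membership) oracle to 0.1%; renderer self-consistency is
  checked by back-projecting every valid pixel onto the generating
  surfaces (< 0.5 mm).
* Scale equivariance (volume × c³ when the whole world, card included,
  scales by c) is asserted with the integration cell scaled along with
  the scene and with scenes kept inside the absolute height band and
  volume cap — those rules are intentionally scale-fixed, and a fixed
  2 mm cell breaks exact self-similarity at the 1–2% level.
* Reference problem sizes: unit tests render at 320×240 (fx = 400) for
  speed; end-to-end checks use 640×480 (fx = 800), camera 400 mm above
  the table; the synthetic study uses 200 participants × 3 meals.
* All stochastic operations take explicit integer seeds and are
  bit-reproducible; report JSON serialises floats at 6 significant
  digits so reruns diff cleanly.

## Known limitations

* Volumes of concave or overhanging shapes are under/over-estimated by
  construction (height fields cannot represent overhangs).
* The card must be flush with the table; items on raised plates shift
  heights by the plate height.
* Card detection targets the synthetic card's bright band; real-image
  detection is a pluggable interface, not solved here.
* The stereo matcher is local (no global smoothness); low-texture food
  yields invalid regions that the height-field integrator simply omits,
  biasing volumes low for glossy or textureless items.
* Detection quantisation (±0.5 px edge phase) bounds the metric scale to
  ~0.3% at the reference geometry; volume errors scale with three times
  that.
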
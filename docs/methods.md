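# Methods

This note records the model, the defaults and the reasoning behind the
design choices, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Camera model and coordinate conventions

The world frame is millimeters with the origin at the base corner of the
gantry's first column, z up; the head travels a 1150 × 840 × 718 mm cuboid.
The camera frame puts the optical center at the origin with x forward
(optical axis), y left, z up. The reference orientation and angle senses
are a genuine design choice (a pan-tilt head admits several conventions):
pan = 0 points the optical axis along world +x and increases
counterclockwise; tilt is measured from the horizontal, positive downward,
spanning [−90°, +90°] — the same 180° physical span as the head's tilt
range. The world→camera rotation factors as a rotation about the vertical
axis by −pan followed by a rotation about the camera's transverse axis by
−tilt; the unit tests verify this against an explicit composition of
elementary rotation matrices.

The projection is purely rectilinear: focal length in pixels
`f = (diag_px/2) / tan(fov_diag/2)` from the diagonal field of view and the
pixel diagonal, with (0.5, 0.5) on the optical axis, u rightward and v
downward (top-left raster origin internally). The 98.7° figure is treated
as the *diagonal* FOV — the camera's spec sheet quotes its FOV range as
diagonal — and is configurable; horizontal/vertical FOVs follow from the
4:3 aspect. No lens-distortion model is fitted; instead an optional margin
exclusion drops boxes that touch the outer fraction of the frame, since
distortion concentrates at the margins. An optical-center offset from the
head attachment point is carried as a configurable 3-vector, default zero.

## Bounding-sphere boxes

Each plant is replaced by a bounding sphere (default radius 90 mm for a
seedling — deliberately generous, absorbing pose/positioning error the way
a physical rig must). At camera distance D a sphere of radius R subtends
half-angle α = asin(R/D); the box is computed from the silhouette cone
d(θ) = c·cos α + sin α·(e₁ cos θ + e₂ sin θ), where {e₁, e₂} is an
orthonormal basis of the plane perpendicular to the center direction c.
The u- and v-extrema over the cone circle reduce to
A·sin θ + B·cos θ + K = 0, solved in closed form (two critical angles per
axis; the four axis-aligned angles are added as cheap guards). Because the
projection of the solid cone is convex and bounded by the cone circle's
image, the resulting box contains the projection of the *entire* sphere
exactly — the dense-sampling tests confirm containment of 10⁴ surface
points per sphere with tightness well under 1% of the image width. Boxes
are clamped to [0, 1]; a box clamped to nothing is reported as absent
rather than an error. Tangent directions that fall behind the image plane
map to ±∞ before clamping, so spheres partially behind the camera
degrade to full-frame extents instead of failing.

Back-projection to the floor (ray–plane intersection at known z) is the
exact inverse of the forward chain for ground-plane points; the suite
checks the round trip to < 10⁻⁶ mm on 1000 random points.

## Route planning and timing

The nested zig-zag divides the volume into slabs along x (default width:
volume extent / 4) and columns along y within each slab; slabs are walked
in +x order, columns serpentine in y with the direction alternating per
slab, and positions within a column are ordered by z with the direction
alternating across consecutive non-empty columns, starting ascending in
the column containing the origin. The serpentine z-direction is tracked
globally across slab changes (the traversal simply continues into the next
slab), and z-ties are broken deterministically by (y, x) ascending so
plans are reproducible. No attempt is made at TSP-optimal routing.

Leg times use a symmetric linear acceleration/deceleration profile in
pulse space: a move of D pulses at peak rate p_r and acceleration a takes
`D/p_r + p_r/a` when it reaches the peak (D ≥ p_r²/a) and `2·√(D/a)`
otherwise; the two branches agree at the boundary. Distances convert to
pulses via the drive chain (0.105 mm/pulse at full stepping). Whether the
three axes move in parallel (leg time = max) or sequentially (sum) is a
profile flag; the default is sequential, matching the conservative
production settings. Pan/tilt time is neglected: the head rotates in
parallel with the gantry move and is almost always faster.

## Synthetic scenes

The generator emulates the rig's study conditions: up to 12 marked floor
positions (4 on the near edge of the volume — half-cylinder of viewpoints —
and 8 interior — full rings), 9 locations imaged per run, seedlings of
eight weed species, uniform keying-blue background (RGB 20/60/200, far
down the CIELAB b axis), arbitrary pan/tilt poses. Plants render as
seeded, lobed rosette sprites lying flat on the floor plane, strictly
inside their bounding spheres (sprite radius is 0.6–0.9 of the sphere
radius). Rendering is exact inverse ray casting — each pixel ray is
intersected with the floor and tested against every sprite — so per-pixel
ground-truth masks are a by-product and are exactly disjoint. Where two
sprites would claim a pixel (tight packing), the smaller normalized radial
coordinate wins deterministically.

What the sprites do *not* model: three-dimensional structure (so plants
never occlude one another vertically), soil or pots, specular lighting,
camera noise, or lens distortion. Passing tests therefore demonstrate the
correctness of the geometry, labeling and keying *machinery*, not
robustness to photographic nuisance factors; with real imagery the chroma
keying would need JPEG-artifact tolerances (±2 levels is a sensible
default) and the purity of crops would additionally depend on plant height.

Viewpoint rings default to (height 450 mm, radius 140 mm, 4 poses): the
radius is chosen so every candidate viewpoint of every marked position
lies inside the travel volume, making a default run exactly
locations × ring-count master images.

## Labeling and label hygiene

Crops use floor/ceil outward rounding of the fractional box to half-open
pixel rectangles, so crops may differ in size. Metadata follows the v1.5
record format; the fractional coordinates are emitted by default in the
dataset's literal convention — (0, 0) at the image's *upper right* corner —
with an explicit `box_origin` field so readers can consume either this or
the conventional upper-left origin. (The literal convention contradicts
the raster convention of mainstream vision libraries; both are supported
and declared rather than silently guessed.) Timestamp collisions within
the same pose number raise instead of overwriting.

A labeled crop can only contain material of a neighboring plant if the two
plants' boxes intersect — any foreign pixel lies in that plant's mask,
which is contained in that plant's box. Since box intersection is exactly
computable here, the pipeline excludes intersecting box pairs from labeled
cropping by default and counts the flagged pairs in the run manifest. In
tight-packing mode (plants packed closer than a sphere diameter, the
imaging-rate-over-quality trade) overlapping boxes are kept *and* flagged,
reproducing the overlap phenomenon that tighter arrangements cause. This
makes label purity a structural property rather than a tuned threshold;
the end-to-end test measures it at ≥ 99% per crop over 50 seeded scenes
with viewpoints drawn from the imaging hemisphere around a plant.

## Segmentation

The CIELAB b channel is encoded 8-bit as b + 128 (blue low, yellow high,
neutral ≈ 128). The production threshold is not fixed a priori: the
default is Otsu's criterion on the b channel (shifted half a level so the
"strictly greater" convention matches the mask's `b ≥ threshold` rule),
overridable by a fixed level. Default cleanup is dilate(3) → fill holes →
erode(3) → Gaussian blur (σ = 1) re-binarized at 0.5, all configurable and
order-preserving. Background subtraction marks a pixel foreground when the
maximum per-channel absolute difference against a pose-identical
plant-free capture exceeds a tolerance (0 for lossless rasters; a few
levels for JPEG).

## Statistics

Accuracy (100·k/n) and binomial standard error (100·√(p(1−p)/n)) are
rounded half-up only for presentation at printed precision; raw values are
returned unrounded. The standard-error formula is the plain binomial one —
it reproduces every published evaluation row we recompute. Clopper–Pearson
intervals come from beta quantiles with the conventional closed endpoints
(lower 0 at k = 0, upper 1 at k = n). Class weights total/count are kept
as exact rationals so the balanced-mass identity c·n_class = total holds
without tolerance.

## Simulated download/cropping times

A software pipeline has no camera download or JPEG cropping stage to
measure, but the production-rate calculator needs t_d and t_c; they are
modeled as per-image linear costs whose default rates are calibrated from
a measured production run (46 min over 2149 masters ≈ 1.28 s/master;
34 min over 3494 subimages ≈ 0.58 s/subimage) and are configurable.

## Problem sizes used in tests

The suite renders at 160×120 to 800×600 rather than the native 4000×3000 —
the renderer is resolution-independent and the geometric assertions are
made in fractional coordinates, so the native size adds cost without
information. The end-to-end labeling check uses 50 scenes at 800×600;
sphere-containment checks use 100 spheres × 10⁴ surface samples; the
interval-coverage check uses 2000 simulated draws at n = 56, p = 0.8.

## Known limitations

- Flat sprites cannot exercise occlusion or plant-height effects on boxes.
- The rectilinear model has no distortion; the margin-exclusion filter is
  a coarse stand-in for calibrated correction.
- The zig-zag planner assumes the slab/column partition is meaningful for
  the pose distribution; for viewpoint sets clustered per plant it is
  merely a reasonable ordering, not an optimal one.
- Edge-position viewpoint half-cylinders face away from the nearest
  boundary face; positions near a corner still lose some candidates to the
  volume filter.
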
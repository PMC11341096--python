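# Methods

## Signal model

A pixel's response to the rotating excitation polarization is
`I_ω = a + b·cos 2(ω − α)`. For the fixed four-angle design
(ω = 0°, 45°, 90°, 135°) the three parameters are overdetermined by the
four measurements, and the classical estimators

    S0 = (I0 + I45 + I90 + I135)/2,  S1 = I0 − I90,  S2 = I45 − I135
    p = sqrt(S1² + S2²)/S0,          α = atan2(S2, S1)/2

are *exactly* the least-squares solution: `a = S0/2`,
`b = sqrt(S1²+S2²)/2`, phase `φ = α`. `fit_pixel_sinusoid` implements
the general linear least-squares fit (valid for any angle set) and the
test suite verifies its equality with the closed form at the four-angle
design to 1e−8 and its global optimality against a phase-grid search.

Conventions and degenerate cases:

* α is axial (period 180°), stored internally in radians in
  [−π/2, π/2) and reported in degrees in [0, 180). Angles are measured
  anticlockwise from the +x axis (x = column index) in a y-up frame;
  raster row order is flipped only at display time.
* Pixels with S0 = 0 have undefined order; pixels with S1 = S2 = 0 have
  undefined azimuth. Both are flagged NaN — never 0, which is a valid
  direction.
* p is *not* clipped at 1: noise can push the modulation amplitude
  above S0, and clipping would bias the signal-to-background analyses.
* The out-of-plane dipole angle θ is not retrievable from this design;
  its sin²θ factor is absorbed into the per-pixel amplitude.

Flat-field correction (optional): per angle, the supplied calibration
stacks are averaged, the average is divided by its own mean (a uniform
flat of any level is a no-op), and the data image is divided by the
result. The correction refuses nonpositive flat pixels rather than
producing infinities.

Custom per-pixel statistics can be registered
(`register_custom_statistic(name, fn)`); they are computed alongside the
standard maps and contribute a per-object mean feature
(`custom_<name>`).

## Segmentation

Both schemes operate on S0 and are intensity-scale invariant.

**Puncta** (near-diffraction-limited spots and short curvilinear
structures): white top-hat (disk radius 8 px) → Gaussian smoothing
(σ = 1 px) → global Otsu threshold → hole filling → area filter
(≥ 10 px²) → 8-connected labeling, one object per component. The Otsu
threshold is computed on a 256-bin histogram, maximizing between-class
variance with ties broken toward the lower threshold; a constant image
yields an empty mask with a warning.

**Filaments** (extended linear structures): multiscale ridge
enhancement — at each scale σ ∈ {1, 2, 3} px, the σ²-normalized most
negative Hessian eigenvalue, clamped at 0 for bright ridges, maximized
over scales — then thresholding at the 0.98 quantile of the enhanced
image, skeletonization, cutting the skeleton at junction pixels (≥ 3
skeleton neighbors), pruning branches shorter than 10 px, and dilating
each surviving branch by 2 px into its object mask. Dilated pixels are
assigned to the *nearest* branch so labels remain a partition of the
mask. The quantile threshold is scene-coverage dependent by
construction; under strong noise it admits short spurious fragments,
which the branch-length and any downstream length filters remove, and
which never contaminate length-based splits at biologically relevant
cutoffs.

The defaults above suit fields of view at ~0.1 µm/pixel; every
parameter is exposed in the configuration.

Mask editing is programmatic: `remove-labels` deletes objects and
compacts the numbering; `add-region` ORs a region into the mask and
rebuilds objects as 8-connected components (bridging regions therefore
merge objects).

## Midline extraction

Elongated objects get a midline — a discrete approximation of the
medial axis — so azimuths can be measured relative to the structure:

1. **Boundary.** The ordered 8-connected perimeter (pixels of
   `mask & ~erosion(mask, 3×3)`), ordered by projection onto the
   sub-pixel iso-contour of the mask, oriented anticlockwise.
2. **Adjustment.** The boundary polygon is offset outward by 1 px
   (round joins), densified to ~1 px vertex spacing, smoothed with a
   circular 5-point moving average, and resampled at 1 px arc spacing.
   The dilation and smoothing suppress pixelation noise that would
   otherwise riddle the Voronoi diagram with spurs.
3. **Interior Voronoi graph.** The Voronoi diagram of the adjusted
   boundary points is computed; finite edges with both endpoints
   strictly inside the polygon form a graph that approximates the
   medial axis.
4. **Path selection.** The midline is the longest geodesic leaf-to-leaf
   path through that graph, found by a two-sweep farthest-point search
   (exact when the interior graph is a tree, which it is for simple
   boundaries; for graphs with cycles the two-sweep result is used
   as-is).
5. **Spur pruning and end extension.** Path nodes whose clearance
   (distance to the boundary polygon) falls below 0.9× the median
   clearance are trimmed from the ends; these are Voronoi branches into
   mask corners and end caps, which sit below the core's
   half-width-level clearance. Each trimmed end is then extended along
   its local tangent until it meets the dilated polygon, pulled back by
   the dilation so the midline terminates on the original outline.
6. **Validity.** If the trimmed core is shorter than max(3 px, 1.5× the
   maximal clearance), the object is near-isotropic (e.g. a disk) and
   is flagged *no valid midline* — tangent extension would fabricate an
   arbitrary diameter. Such objects keep their image-frame azimuth but
   have no midline-relative features.
7. **Tangents.** The path is smoothed (5-point window, endpoints
   pinned), resampled at 1 px, and given central-difference tangents
   (axial degrees). Every object pixel takes the tangent of its
   Euclidean-nearest midline point (ties to the lower index), and
   `α_midline = (α_image − tangent) mod 180`.

Measured behavior (recomputed by the test suite and acceptance script):
a 40×4 px bar yields a 39 px midline with tangents within 0.01° of the
bar axis; an S-shaped ribbon of width 5 px built from a known parametric
curve is recovered within 0.6 px Hausdorff distance and 0.5% arc
length; arc length is stable under rotation to within 1%.

## Circular statistics

Azimuths are axial, so all statistics use the double-angles transform:
angles are doubled, the weighted circular resultant is computed, the
mean direction is halved back, and the circular standard deviation is
reported on the axial scale as `s0 = ½·sqrt(−2 ln R̄)` with R̄ from the
doubled sample. The halving convention is fixed and documented rather
than configurable; s0 therefore ranges up to ~40° for realistic samples
and diverges (flagged NaN) as R̄ → 0. Polar histograms duplicate each
angle at θ and θ + 180° so both equivalent directions appear; bin
counts sum to 2n. Means are undefined (NaN) when R̄ < 1e−9, e.g. the
orthogonal pair {0°, 90°}. Weighted variants support intensity-weighted
object azimuths; features are unweighted by default.

## Object features

Per object: area (pixel count), perimeter and eccentricity (standard
region properties of the 8-connected mask), midline arc length L in µm,
mean S0, mean order p̄ (arithmetic mean over defined pixels), axial
mean azimuths ᾱ_image and ᾱ_midline, azimuthal disorder s0, and the
local signal-to-background ratio: mean object S0 divided by mean S0 in
an annulus (dilation by buffer+annulus minus dilation by buffer,
defaults 2+2 px) from which *all* object pixels in the image are
excluded, so neighbors do not contaminate the background estimate. An
object filling the frame, or with a fully occupied annulus, has
undefined S/B. The mean-based background (rather than median) is the
documented default.

## Analysis layer

Projects hold groups (conditions/replicates) of images; the pipeline
per image is flat-field → maps → segmentation → features/midlines, with
per-image failures logged and skipped. Object filtering is a
conjunction of scalar predicates; labeling rules must partition the
population (overlaps and gaps are errors). The filament short/long
split uses the persistence length of phalloidin-stabilized F-actin,
L_p = 17.5 µm, with L ≥ L_p inclusive on the long side. k-means
clustering (k-means++; 20 restarts; 300 iterations; tol 1e−6; fixed
seed) operates on z-scored features by default and renumbers clusters
so cluster 1 has the lowest mean of the first feature — with S/B first,
cluster 1 is the low-S/B population. On small 1-D samples, 20 restarts
occasionally return a local optimum whose inertia is within a fraction
of a percent of the exhaustive best split; the acceptance script
reports the observed agreement fraction.

## Synthetic scenes

The generator renders `I_ω = B_g + A·(1 + p·cos 2(ω − α))/2` per pixel,
then optional Gaussian blur (optics) and then noise (detection):
additive Gaussian or Poisson shot noise, seeded. The half-amplitude
parameterization makes S0 = 2B_g + A and makes the recovered order
equal `A·p/(A + 2B_g)` exactly in the noiseless case — the background
dilution that the S/B analyses quantify. Default conditions: puncta of
radius 3 px with amplitude 90 on background 10 (S/B = 5.5) and order
0.8 at 0.1 µm/pixel, ≥ 10 px separation; S-ribbons of width 5 px from a
one-period sine curve; straight filaments of width 4 px with exact
planted metric lengths. Ribbons and filaments are **butt-capped** (cut
flat, normal to the curve, at its endpoints) so the generating curve is
exactly the tube's medial axis — the property midline recovery is
tested against.

What the generator does *not* emulate: vectorial high-NA
depolarization, photobleaching between the four frames, camera fixed-
pattern noise, out-of-focus background structure, and curved/branched
filaments. Passing recovery tests on these scenes therefore validates
the pipeline's arithmetic and geometry, not its robustness to every
real-microscope artifact; flat-field correction is exercised with
synthetic gradients only.

## Visualization

Order-intensity overlay (order colormapped, normalized intensity as
alpha), azimuth-order-intensity HSV (hue = α with period π so opposite
directions share a color, anchored at α = 0 → hue 0; saturation =
order; value = normalized intensity; undefined azimuths desaturated),
azimuth sticks (one segment per sampled object pixel, oriented at
α_image, colored by a 180°-cyclic map of α_image or α_midline), and
axial polar histograms. Intensity/order normalization defaults to the
0.1–99.9 percentile range per image, configurable to the extremes. All
renders are deterministic.

## Numerical notes and limitations

* Arc lengths are invariant under transposition/90° rotation only to
  ~1e−2 px: the buffer arcs and Voronoi vertex orderings of the
  geometry library are not bit-symmetric under coordinate exchange.
* The midline of a self-occluding or branched object is a single
  longest path; side branches are ignored by construction. Branched
  structures should be segmented with the filaments scheme, which
  splits at junctions first.
* `fit_pixel_sinusoid` snaps numerically constant responses
  (b ≤ 1e−12·max|I|) to amplitude 0 and phase 0.
* Problem sizes in the test suite and acceptance script (256–512 px
  frames, 20–50 scenes, 10⁴-sample oracles) were chosen so the entire
  verification runs in well under a minute while keeping every
  statistical check comfortably away from its decision boundary.
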
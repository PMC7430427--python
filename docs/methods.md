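# Methods

This note records the models, numerical choices and validation design
behind `mh3d`, at the level of detail a maintainer needs to change a
default responsibly.

## Coordinate and unit conventions

Volumes are indexed `(x, y, z)`: X lateral within a B-scan, Y depth
(increasing from vitreous toward choroid), Z across B-scans.  Voxel
indices are 0-based; the physical position of a voxel is
`index × spacing` with the origin at the top-left of the first B-scan.
All algorithmic length scales (kernels, curvatures, distances,
tolerances) are micrometres, never raw voxels: clinical protocols are
strongly anisotropic (typically 5.47 × 3.87 × 30 μm), and a voxel-space
kernel would be six times wider across B-scans than within one.

## Reference surfaces

Per A-scan column, the RPE is the dominant bright band: the argmax of
the depth profile after Gaussian smoothing along Y (σ = 1 voxel), with
parabolic sub-voxel refinement.  The ILM is the first depth where the
smoothed profile exceeds a configurable fraction (default 50 %) of that
column's RPE peak, refined by linear interpolation of the crossing.
Columns whose band contrast is below 5 % of the global range count as
undetectable; if more than 5 % of columns are undetectable the
estimation fails loudly.  Two post-passes make the maps usable over a
hole:

* columns whose ILM–RPE separation falls below 60 μm are the open top of
  the hole (the first interface there is the RPE itself); their ILM is
  inpainted from surrounding retina by nearest-value seeding plus
  Laplacian relaxation;
* localized ILM depressions narrower than 900 μm (the dip where a hole
  wall overhangs) are bridged by a grey-scale morphological opening of
  the depth map, so the ILM reference spans the opening the way the
  inner retinal surface does around it.

Both maps are median-filtered (5 px) and Gaussian-smoothed (2 px)
laterally, and ILM < RPE is enforced.  These detectors are designed for
band-structured volumes (and are accurate to ≤ 1 voxel on them); real
pathology would want a pluggable replacement, which is why the
parameters live in one `SurfaceParams` object.

Flattening shifts each column by a whole number of voxels so the RPE
lands on a common plane.  No interpolation: the voxel population is
preserved exactly, the operation is invertible (padding, never
cropping), and "RPE-parallel section" becomes "grid slice".

## Segmentation

**Seed.**  Voxels inside the ILM–RPE band below the 20th intensity
percentile of the band, opened in-plane with a 3×3 footprint (in-plane,
so the voxel-thin shelf where the hole wall meets the RPE survives),
largest connected component.  φ starts as the signed Euclidean distance
to the seed, negative inside.

**LGDF evolution.**  Intensities are min–max normalised (this gives the
documented invariance to global affine intensity rescaling).  At each
iteration the interior/exterior local Gaussian statistics are computed
under a Gaussian window of physical scale σ = 16 μm via six separable
convolutions; the data force at a voxel is the difference of the local
Gaussian negative log-likelihoods, weighted λ₁ (interior) and λ₂
(exterior).  A mean-curvature length penalty (μ) and a distance
regulariser (ν, Laplacian-minus-curvature form) complete the update.
Defaults: λ₁ = λ₂ = 1, μ = 10, ν = 0.05, Δt = 30, ≤ 120 iterations per
scale, variance floor 10⁻³ on the normalised scale.  μ was chosen as the
largest length penalty that does not erode the sharp rim of a noiseless
two-level phantom (μ ≈ 60 visibly rounds it); the variance floor keeps
the log-likelihoods finite on piecewise-constant data, where the local
variance would otherwise collapse and produce forces ~10⁵ that no step
size can integrate.

**Energy guard.**  Each step is accepted only if the total energy (data
+ length + regulariser, evaluated with freshly recomputed statistics)
does not rise by more than 10⁻⁶ relative; otherwise the step is retried
with a halved Δt (force cached, so retries are cheap), and Δt recovers
by ×1.2 after acceptances.  This makes the recorded energy non-
increasing over accepted iterations by construction.  The flip side:
when the data force vanishes identically (exactly constant intensity),
strict descent of the *discrete* energy stalls in lattice-scale local
minima after a genuine initial shrink — the smoothed interior measure
decreases monotonically, but the interface does not collapse the way an
unguarded curvature flow would.  With any real data force this regime is
never entered.

**Multiscale.**  Lateral (X, Y) block-mean downsampling by factors
(4, 2, 1); Z is already coarse and is never downsampled.  φ is in μm, so
the converged coarse field upsamples directly (linear interpolation) to
warm-start the next scale.  Convergence: relative change of the interior
volume below 10⁻⁴ across 10 iterations.  Divergence (interior > 90 % of
the grid, or empty) aborts with the failing scale and iteration.  The
driver crops to the depth band spanned by the surfaces (plus margin)
before evolving — the hole lives there, and it halves the work.

**Curvature surface cut.**  The segmented region blends into the
vitreous through the hole's open top.  The cut (i) locates the rim as
boundary voxels within ±2 voxels of the ILM whose mean curvature (of the
smoothed indicator, window 15 μm) exceeds the 90th percentile of
boundary curvature, keeping the rim component that encloses the region
centroid; (ii) anchors the cap to the ILM with a rim-derived sub-voxel
depth offset (clamped to ±½ voxel — the clamp is what makes the cut
exactly idempotent) and removes everything above it; (iii) closes the
opening by filling columns that reach within 3 voxels of the cap, and
(iv) caps the base at the RPE plane.  Both caps *extrapolate the wall
slope*: the bright RPE band hides the last rows of the hole from any
intensity criterion, so the hidden rows are widened row-by-row by the
wall's measured per-row growth (area increment ÷ Crofton-corrected
perimeter of the last visible section) instead of dropping a vertical
cylinder.  Growth is applied with sub-pixel-aware dilation (a pixel
joins when its centre is within reach of the region *boundary*, half a
lattice step beyond the nearest interior centre), otherwise small
growths would quantise to zero on the 30 μm axis.

## Morphometry

Sections are grid slices of the flattened mask, measured on the largest
in-plane connected component.  Feret diameters are rotating calipers on
the convex hull of pixel-corner points (a 1-pixel region has extent
dx × dz); the maximum is the hull diameter, the minimum the smallest
width over hull edges (attained perpendicular to an edge for any convex
set).  **Meridians are reported from the second-moment principal axis**
(axial convention, mod 180°), not from the extremal chord: the
directional extent is flat near its extremum, so on a 30 μm Z pitch the
chord direction wanders by 10–20° on mildly elliptical sections while
the moment axis stays within ~2°; for ellipse-like sections the two
definitions coincide.  Base meridians are additionally stabilised by an
area-weighted axial (doubled-angle) mean over sections within 3 dy of
the base.  The minimum area is searched over the central 20–90 % of the
hole height, ties breaking toward the RPE.  Hole height is RPE plane to
the highest mask voxel; retinal height is the maximal ILM elevation over
the rim ring (3 px wide) outside the base footprint.

Volume is voxel count × voxel volume.  Surface area meshes the zero
level of the mask's signed Euclidean distance field (physical sampling,
marching cubes), after smoothing the field with a Gaussian of half the
finest voxel pitch: the signed-distance representation keeps flat faces
flat, and the half-pitch smoothing suppresses the oblique-staircase bias
(a raw binary iso-surface overestimates a sphere's area by ~9 % at 5 μm
sampling) without erasing resolved features.  Measured biases at 5 μm
isotropic sampling: sphere +3 %, cube −4 %, cylinder +1 %, cone +2 %;
on the anisotropic phantom rasters, within ~3 % of the analytic truth.

IVTS classes close each band on its upper edge (≤ 250 small,
250–400 medium, > 400 large), a declared convention since the published
band edges leave exactly 250 μm unassigned.  The truncated-cone
surrogate is V = πh(d₁² + d₁d₂ + d₂²)/12 for parallel circular faces of
diameters d₁, d₂.

## Phantoms and what they do (not) show

The generator renders a three-band volume (vitreous 25, retina 160, RPE
band 240, sub-RPE 90, arbitrary reflectivity units) with a 24 μm bright
band — wide enough that depth smoothing cannot dilute it below the
retina plateau, consistent with the RPE/Bruch's complex in OCT — and
carves the hole as the solid swept through base, waist and top ellipses
with piecewise-linear interpolation of semi-axes, meridian (shorter-arc,
mod 180°) and centre.  The truth mask is the raster of that solid down
to the RPE plane; truth parameters come from closed forms (ellipse area
and Feret, misalignment) or quadrature (volume by per-segment Simpson,
exact for the quadratic integrand; lateral surface by a triangulated
sweep at 0.5 μm height steps with the meridian sequence unwrapped so the
mesh cannot twist).  Speckle is multiplicative Gamma noise with mean 1
and SD *s* — the standard first-order OCT speckle surrogate.

The study geometry is the clinical macular cube downsampled ~5× laterally
(160 × 120 × 49 voxels at 10.94 × 7.74 × 30 μm, ILM at 150 μm, RPE at
450 μm), keeping the clinical 30 μm line spacing and its anisotropy;
a full segmentation then runs in seconds, so the whole validation suite
runs on one CPU in minutes.  The recovery suite cycles cylinder,
hourglass, rotated-ellipse and tilted archetypes with seeded jitter on
sizes, waist height, meridians and tilt; elliptical archetypes keep an
axis ratio ≳ 1.2 so their meridians are identifiable (a circle's Feret
meridian is undefined, so meridian recovery is only asserted where the
analytic axis ratio is ≥ 1.15).

What passing phantoms does **not** show: robustness to real retinal
sublayers, vasculature shadows, motion between B-scans, operculum
overhang in the intensity sense (an operculum blob can be rendered, but
it is disjoint from the hole and removed by the largest-component rule),
eye-specific RPE curvature, or detector behaviour on non-band-structured
pathology.  The published accuracy of this class of algorithm against
manual expert segmentation on clinical data cannot be reproduced here;
the phantom suite is the property-based stand-in.

## Statistics layer

Differences are `a − b` (first series minus second), stated in every
output.  Bland–Altman limits are mean ± 1.96 SD; the bias CI uses the
t quantile (n−1 df) with SE = sd/√n, each limit's CI the classical
approximation SE = sd·√(3/n).  Spearman and Shapiro–Wilk delegate to
scipy (Shapiro–Wilk is verified in tests against values computed
independently with R's `shapiro.test` to 10⁻⁶).  The quadratic-vs-linear
comparison is a nested-model F test (1, n−3), equivalent to the t test
on the x² coefficient.  Marginal homogeneity of a size-class crosstab
uses the Stuart–Maxwell statistic d′S⁻d (χ², k−1 df), implemented
directly (no pre-installed package exposes it) with a pseudoinverse for
degenerate covariances and the convention p = 1 for a purely diagonal
table.  The quadratic-power simulation uses x ~ U(100, 900) μm,
y = 0.5x + 0.002x² + N(0, 100²), n = 100 — a curvature on the scale of
the measured base-vs-minimum diameter relationship, strong enough that
the test should essentially always find it.

## Validation design

Every non-trivial operator has an independent oracle: rotating calipers
vs a 0.1° directional-extent sweep on random convex polygons (bounded
aspect ratio ≥ 0.4, because on a sliver the width minimum sits at a kink
and the sweep's own angular resolution error exceeds the 0.5 % band
being checked); voxel geometry vs closed forms for sphere, cube,
cylinder and cone (caps placed off the voxel grid — a grid-aligned cap
picks up one whole extra voxel slab, the degenerate worst case of the
inclusive raster convention); the truncated cone vs slab quadrature;
analytic phantom volume vs fine trapezoid quadrature; Bland–Altman and
Stuart–Maxwell vs direct formulas; Shapiro–Wilk vs R.  End-to-end
recovery asserts, per phantom: every diameter within max(2dx, 2dz),
well-posed meridians within 5°, volume and surface area within 5 %,
misalignment within 2dx, Dice ≥ 0.98 noiseless and ≥ 0.90 at speckle
s = 0.2, and non-increasing energy over accepted iterations.  These are
voxel-scale tolerances: individual seeds can land a single coarse-axis
voxel (30 μm) or a degree past them on particular shapes, which is the
quantisation floor of the 30 μm line spacing, not a convergence failure.

## Known limitations

* Surface detectors assume a band-structured volume; real data needs a
  replacement behind `SurfaceParams`.
* The base of the hole inside the bright RPE band is geometric
  extrapolation, not measurement — any intensity method shares this
  blind spot.
* Meridians of near-circular sections are intrinsically ill-posed; the
  reports still contain them, but they should be interpreted together
  with the min/max diameter ratio.
* The energy-guarded evolution trades a little convergence speed for a
  provable monotonicity log; on pathological flat-energy inputs it
  stalls rather than over-smooths.
* Whole-voxel flattening quantises the RPE plane to dy; sub-voxel
  flattening would interpolate intensities and break bit-exactness,
  so it is deliberately not the default.
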
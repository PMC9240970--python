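# Methods

`walltomo` quantifies the nanoscale architecture of plant primary cell
walls as seen in cryo-electron tomograms: the 3D geometry and axial
orientation statistics of traced cellulose fibers, and the volume
occupancy of the reticulated inter-fiber "meshing" (largely
homogalacturonan pectin) isolated by segmentation-map subtraction.
This note documents the models, conventions, parameters and numerical
choices, and what the synthetic validation does and does not show.

## Coordinate and unit conventions

All internal coordinates are nanometres; conversions from pixel or
Angstrom units happen only at I/O boundaries.  Volumes are indexed
`[z, y, x]` with 0-based voxel indices; a point's physical position is
its voxel index times the voxel size (voxel-centre convention).  In
synthetic phantoms z = 0 is the wall surface and depth increases with
z.  The reference axis for fiber angles is the cell long axis, a unit
vector in the tomogram xy-plane.

## Per-fiber geometry

A fiber is an ordered 3D polyline ("contour").  The processing chain
for one tomogram is:

1. **Out-of-plane filter.**  Contours whose end-to-end chord is
   inclined more than 70 degrees to the xy-plane are reconstruction
   artifacts, not fibers, and are removed.  The angle is defined on
   the chord, the simplest reading of an "out-of-plane angle of the
   contour"; a zero-length chord (closed contour) is treated as
   maximally out-of-plane and removed with its own diagnostic.  By
   default the filter runs in the as-reconstructed frame, before the
   milling rotation; the alternative order is a config switch.
2. **Milling rotation.**  The volume is rigidly rotated about the
   y-axis by the nominal FIB milling angle to undo the flattening of
   the reconstruction.  Sign convention: positive angle tilts +x
   toward -z (`x' = x cos a + z sin a`, `z' = -x sin a + z cos a`), so
   the lamella leading edge stays shallow.  Rotation is an isometry;
   tests assert pairwise distances, lengths and curvature radii are
   preserved.
3. **Vertical-artifact trimming.**  Punctate signal propagates
   artifactual z-parallel lines.  Per trace, the second-moment tensor
   of unit tangents is computed; traces with ZZ component above 0.8
   (default), or |XZ| above an optional band limit, are removed.
4. **Canonical direction.**  Each trace is oriented so its first point
   has the lower y-coordinate (ties broken by lower x, then lower z),
   giving slopes and fiber vectors a common sign convention.  The
   operation is idempotent.
5. **Spline resampling.**  Points exported from tracing software are
   unevenly spaced, which would bias curvature and slope averages.
   Each trace is reparameterized by arc length using an interpolating
   spline (order min(3, n-1), chord-length parameterization) and
   resampled at 1 nm; endpoints are preserved exactly.

Per-fiber statistics on the canonicalized, resampled polyline:

- **Length** — sum of distances between neighbouring points.
- **Curvature radius** — mean over consecutive point triples of the
  Menger circumradius `R = d12 d23 d13 / (4 area)`.  Triples with
  triangle area below 1e-6 nm^2 are excluded from the average to avoid
  division blow-up; a fully collinear fiber reports an infinite-radius
  flag, fewer than 3 points reports NaN.
- **Slope** — unweighted mean of local `dz / dxy` over consecutive
  pairs (after 1 nm uniform resampling, unweighted and arc-length
  weighted means coincide to first order).  Locally vertical pairs
  are excluded.
- **Mean z-height** — average of point z-coordinates.
- **Angle to the cell axis** — the fiber vector f points from the
  lower-y end to the higher-y end; the clockwise angle to the axis c
  is `(-atan2(cx fy - cy fx, cx fx + cy fy)) mod 180`, in [0, 180).
  A fiber with no xy extent is flagged undefined.

**Depth in the wall.**  A tomogram's depth below the wall surface is
`d tan(alpha)` from the nominal milling angle alpha and the projected
distance d to the lamella leading edge, with `d sin(alpha)` available
as a config switch for d measured along the milled face (the phrasing
"projected distance" admits both readings; top-view projection is the
default).

## Axial orientation statistics

Fiber orientations are axial: theta and theta + 180 are the same
direction.  All fitting is done on the doubled circle `phi = 2 theta`,
where axial data become ordinary circular data; a Gaussian mixture on
raw degrees would break at the wrap.  The model is a k-component von
Mises mixture fitted by EM (convergence |delta loglik| < 1e-8 or 500
iterations, 8 deterministic seeded restarts with component means
initialized at data points — an initialization that makes the fit
exactly equivariant under global rotation of the data).  Component
concentrations use the standard resultant-length approximation for the
von Mises MLE, capped at 1e4 to keep point-mass data finite; because
this update is approximate, the likelihood is monotone only to ~1e-6,
which the convergence test accepts.  Modes are component mean
directions halved back to [0, 180), not histogram peaks.

**Bimodality.**  The field practice is a mixture fit plus a dip test
with unreported thresholds; here the criterion is explicit: a
distribution is bimodal when BIC(k=1) - BIC(k=2) >= 6 *and* the axial
mode separation is >= 20 degrees *and* the minor weight is >= 0.15.
The separation and weight guards prevent the two-component fit from
splitting one broad mode.  Hartigan's dip statistic with a bootstrap
p-value is provided as a diagnostic only.  Verdicts are
criterion-dependent; the recovery harness shows that for two modes
>= 60 degrees apart with spread <= 10 degrees and n = 1000 the modes
are recovered within 3 degrees and declared bimodal in >= 95% of
seeds, with <= 10% false positives on unimodal samples.

**Layering pattern.**  Fibers are assigned to their maximum-posterior
mode; the overlap coefficient `int min(f1, f2)` between the two modes'
mean-z kernel density estimates (Gaussian kernel, Silverman bandwidth)
classifies the stack: staggered below 0.25, overlapped above 0.75,
staggered-overlapped between, unimodal whenever the angular verdict is
unimodal.  The thresholds are documented, tunable constants chosen to
separate the generator's canonical patterns with margin.  Known
limitation: with many thin alternating layers the per-mode z
distributions genuinely interleave across the whole stack and the KDE
overlap is large, so a finely laminated staggered wall is reported as
staggered-overlapped or overlapped; the classifier resolves layering
at the scale of the KDE bandwidth, not individual lamellae.

## Meshing segmentation and occupancy

The pipeline consumes two probability maps per tomogram: one trained
on fibers only and one on all features.  The fiber map is thresholded
into a mask (>= by default; > exposed); the mask (optionally dilated,
default 0) is subtracted from the all-features map, and the remainder
is thresholded into the meshing mask — everything that is not fiber is
assumed to be meshing.  The two masks are disjoint by construction.
Volume occupancy is voxel count times voxel volume; this replaces the
contour-cylinder volume of the original tooling, a deliberate
deviation expected to shift absolute ratios but not trends, so
published absolute ratios are not comparable, only their depth
behaviour.  Thresholds are explicit configuration, never automatic:
the right level depends on how the upstream map was produced and is a
human judgment this pipeline does not emulate.  For the synthetic
phantoms the validation threshold is 0.45: the rendered tube takes
discrete intensity levels around the half-maximum radius (0.508 and
0.406 at 2 nm voxels), and 0.45 sits centrally in that gap, so the
clean captured set equals the half-max set while additive-noise flips
at the boundary stay balanced.

Depth profiles sort per-tomogram occupancy results by depth and report
mean +/- sd of the meshing/fiber ratio per treatment; an explicit
exclusion list is honoured and logged, never silent.

## Fiber tracing

A functional analog of template-matching filament tracing.  Stage 1
(cylinder correlation) scores every voxel by normalized
cross-correlation against a soft cylinder (Gaussian cross-section with
half-maximum radius equal to the outer cylinder radius, evaluated
inside a mask cylinder of 125% that radius) over an orientation grid;
in-plane angles sweep [0, 180) at the angular step, out-of-plane
inclinations default to {0} because the fibers of interest are nearly
horizontal and steep traces are removed downstream anyway (the list is
configurable).  Correlations at voxels whose local masked variance or
energy is at numerical-noise level are flagged undefined (NaN) rather
than zero.  Stage 2 (line tracing) seeds at local correlation maxima
above the seed threshold, visited in descending correlation with
lexicographic tie-breaks (a total order, making the tracer fully
deterministic), and extends each line bidirectionally: at each step
the candidate directions are in-plane rotations of the current heading
inside a cone of half-angle 37 degrees; the best-correlated candidate
is taken unless its correlation falls below the continuation
threshold, and the heading is then blended with the local
best-template orientation using the direction coefficient as convex
weight (the upstream tool's semantics for this coefficient are
unpublished; convex blending is this implementation's documented
interpretation).  Lines shorter than the minimum length are discarded
and no accepted line may approach another within the minimum line
distance (default twice the cylinder diameter).  Parameter names and
defaults mirror the published configuration (cylinder length 50 px,
angular sampling 5, minimum line length 60 px, direction coefficient
0.3, cone look-ahead 80 px with 10% minimal step); internals are
original.  Missing-wedge compensation is accepted as a no-op flag for
config compatibility.

## Synthetic phantoms

The generator emulates the statistical structure the analysis assumes,
so every stage is testable without microscope data.

- **Fiber fields**: horizontal layers of fibers whose in-plane angles
  follow axial von Mises noise (on the doubled circle, respecting the
  180-degree periodicity) around one or two modes, by default +/- 45
  degrees to the reference axis with 8-degree spread.  Four stacking
  patterns: staggered (alternating single-mode layers), overlapped
  (both modes at all heights), staggered-overlapped (alternating with
  spill-over half a layer into neighbours), unimodal.  Fibers are
  straight chords or constant-curvature arcs (the arc is symmetric, so
  the end-to-end angle equals the drawn angle exactly); z rises
  linearly with in-plane arc length at a slope drawn N(0, slope_sd),
  default sd 0.02 matching near-horizontal trajectories.  Kinked
  fibers are out of scope.  Polylines are sampled at <= 2 nm spacing;
  every fiber appears exactly once in the emitted truth table.
- **Meshing**: short isotropic segments (20-60 nm, free parameters —
  no quantitative meshing morphology is available to emulate) with
  optional branching, whose midpoint density decays exponentially with
  depth.  The exponential is the simplest monotone law consistent with
  a rapid drop in meshing abundance around 1 um depth; the
  characteristic depth is the parameter.
- **Rendering**: fiber and meshing centrelines become soft tubes whose
  intensity is a Gaussian of distance to the nearest centreline
  (computed by Euclidean distance transform of the rasterized
  centrelines), with sigma set so the half-maximum radius equals the
  nominal tube radius and axis intensity exactly 1.  The all-features
  map is the voxel-wise maximum of fiber and meshing tubes.  Maps are
  clipped to [0, 1]; optional PSF blur, then white Gaussian noise,
  are applied last (noise may under/overshoot the clip range, as CNN
  maps of noisy data do).  Missing-wedge anisotropy, CTF and dose
  effects are *not* simulated — the downstream mathematics never
  models them, so passing tests demonstrate algorithmic correctness,
  not robustness to real cryo-ET artifacts.  A memory budget guards
  the voxel grid size.

Ground truth for occupancy uses the same nominal radii: a voxel is
truly "tube" when its centre is within the radius of a centreline
(distance-transform voxelization), with fiber-overlapping meshing
voxels removed exactly as the subtraction stage does.

Determinism: every generator takes an explicit seed and identical
seeds give bit-identical outputs; the pipeline threads one top-level
seed through all stages and records it in the run manifest together
with a content hash of every output file.

## Problem sizes used in validation

The test suite and the acceptance script run at desk scale, chosen so
each check still measures what it claims: analytic arcs of radius
50-500 nm sampled at 1 nm for the curvature estimator; 1000 random
fibers for filter equivalence; 100 (test suite) or 20 (acceptance
script) seeds of n = 1000 angles for the mixture recovery rates; a
400 x 400 x 200 nm phantom at 2 nm voxels (4M voxels, ground-truth
occupancy ratio ~0.37) for the meshing algebra; and a 340 x 340 x 66 nm
staggered phantom at 2 nm voxels (~140 generated, ~70 traced fibers)
for the tracing integration, with tracing parameters scaled to that
template size (cylinder length 9 px, radius 1.75 px) while keeping the
published defaults in the API.

## I/O formats

Trace tables in three text dialects (documented in `walltomo.io`):
`xyz_csv` (trace_id, point_index, x, y, z), `point_segment_tsv`
(point and segment sections modelled on tracing-software exports,
replacing the original binary-export reformatting step), and
`imod_model_text` (object contour x y z).  Binary IMOD/Amira files
are not parsed.  Volumes are MRC2014 (modes 0, 1, 2, 6; voxel size
from the header cell parameters), read and written by a compact
in-package implementation validated against an independent reader in
the tests.  Per-tomogram context (milling angle, voxel size, cell-axis
angle, projected distance, scale, treatment) is YAML or JSON.  All
readers reject non-finite coordinates with a diagnostic naming the
offending line.

## Profilometry and morphometrics

Cross-sectional diameters: transects of configurable length are
sampled perpendicular to a path traced along the fiber (step 1 px,
length 30 px, thickness 10 px by default), averaged over thickness
along the axis orthogonal to the transect plane (z for a volume — the
upstream definition of "thickness" is not recorded; this is the
documented choice) and over stations, double-normalized
(`(v - min)/(max - min)`), and the FWHM is read between the outermost
0.5-crossings bracketing the global peak on a 0.5-px upsampled
profile — outermost crossings make the width robust to shoulder
wiggles.  A peak at the profile border is an error, not a guess.
Whether to normalize per profile or per average is ambiguous in the
source procedure; the average-then-normalize order is implemented.

Cell aspect ratios: outline image -> Gaussian blur (sigma 2 px) ->
re-binarize -> skeletonize to 1-px walls -> label enclosed regions ->
aspect ratio = major/minor axis of each region's second-moment
ellipse (the definition used by the standard particle-analysis tool;
not a bounding box).  Border-touching regions are discarded.  The
synthetic brick-wall mosaic tiles each row exactly so every enclosed
region has a truth row.

## Known limitations

- Absolute occupancy ratios are not comparable to cylinder-volume
  based numbers; only trends and synthetic-truth recovery are claimed.
- The layering classifier cannot resolve lamellae thinner than the
  KDE bandwidth (see above).
- The tracer is a functional analog, not a clone; it is validated on
  rendered phantoms, not against the proprietary tool's outputs.
- Bimodality verdicts depend on the documented BIC criterion; other
  criteria may classify borderline tomograms differently.
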
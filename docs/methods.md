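# Methods

This note documents the models, conventions and numerical choices behind
`torsometry`, and what the synthetic test bed does and does not establish
about real scan data.

## Coordinate conventions

All meshes are normalised on load to an internal frame with *z* the vertical
body axis (superior positive) and +*y* anterior; contours are ordered
counterclockwise as seen from superior. "Standard" polar angles in a slice
put 0° at +*x* and anterior at +90°, so the posterior midline is −90°.
After alignment the grid angle θ is measured from the spinous process (SP):
θ = 0° at the SP, 0°→180° the right body side (counterclockwise), 0°→−180°
the left; aligned Cartesian coordinates are *x* = *r* sin θ, *y* = −*r* cos θ
(SP at the bottom, anterior at the top).

The angular grid runs in 1° steps over −180°…+180°. The ±180° node is one
physical point (the anterior midline) stored twice for wraparound, so the
mean radius *r*<sub>m</sub> — and hence the invariant that relative radii
average to exactly 100 — is computed over the 360 distinct angles.

## Vertebral levels

Only C7, T8 and L5 are inputs (identified on the scan by a specialist; the
package never detects them). Intermediate levels are equally spaced: 8 equal
intervals from C7 to T8 (C7, T1…T8) and 9 from T8 to L5 (T9…L5), reproducing
the landmark heights exactly. This is the simplest reproducible rule that
honours all three landmarks; real intervertebral spacing is not uniform, and
users with better per-level height estimates can supply contours directly.

## Slice extraction

The mesh is cut by a horizontal plane per level (trimesh's plane section).
When several closed loops result — torso plus arms — the loop of largest
enclosed area is kept; the torso dominates any limb cross-section. Open
polylines are rejected rather than repaired. Arm fragments *connected* to
the torso loop can be removed by per-level angular masks about the contour
centroid (replacing manual editing); the removed span is bridged by a
straight chord sampled at the native point spacing and recorded, and masks
totalling ≥ 180° are rejected as unanalysable.

## SP detection

The SP is the radius minimum within a posterior search sector (default
−150°…−30°, i.e. ±60° about the posterior midline). Restricting the search
keeps waist concavities and anterior features out of play. Exact ties break
towards the sector midline; a near-flat minimum (within 0.1 % of
*r*<sub>m</sub>) spanning more than 30° is flagged low-confidence and the
midline is returned (the behaviour for a featureless circle).

The grid minimum is refined to sub-degree precision with a parabola through
its two neighbours. Without refinement the detected SP hops in whole-degree
steps as the centroid drifts with growing deformity, which injects
discontinuous frame rotations into otherwise smooth parameter responses; the
landmark is continuous, so the detector should be too.

Two caveats are intrinsic to minimum-radius detection and documented by
tests rather than hidden: (1) on the sloped posterior baseline of a
superellipse, a broad shallow dip placed off the midline has its *surface
minimum* pulled towards the midline by roughly (baseline slope)·σ²/depth, so
exact center recovery requires a reasonably sharp dip; (2) under radial
noise the raw minimum jitters by a degree or two. For noisy scans an
optional circular moving-average pre-filter is available
(`sp_smooth_window`, odd degrees; off by default). The default window used
for the noisy synthetic scans is 7°, matching the angular scale of the SP
dip (sd 8°): wider windows suppress noise further but start biasing
off-midline dips.

## Alignment

Step 1 finds θ\* maximising the centroid diameter d(θ) = r(θ) + r(θ+180°) on
the grid and makes that diameter horizontal (ties, e.g. circles, break
towards the diameter already closest to horizontal). Step 2 applies the fine
rotation placing the SP directly below the centroid, choosing whichever of
the two horizontal orientations needs the smaller correction; corrections
beyond 45° are flagged as a strong disagreement between SP detection and the
principal direction. The net rotation is applied in a single periodic linear
interpolation of (θ, r) onto the aligned grid, so no double-resampling error
accumulates. Linear interpolation reproduces any piecewise-linear radius
function exactly and is node-exact whenever the rotation maps sample angles
onto grid angles; no smoothing is applied before resampling.

Non-star-shaped contours (a centroid ray crossing the boundary twice) keep
the largest radius per 1° bin — the outer silhouette a scanner sees — with a
logged warning. Angular gaps wider than 10° (typically masked arms) are
interpolated across and recorded.

## Parameters

* **Relative radius** RR(θ) = r(θ)/*r*<sub>m</sub> × 100, split into right
  (0…180°) and left (0…−180°) branches of 181 entries sharing the SP and
  anterior-midline points.
* **R²**: pairs matched by equal |θ| (181 for full sides, separation+1 for
  backside sectors; the shared SP and ±180° pairs are included by default and
  configurable) are fitted by ordinary least squares with the right branch
  as abscissa. R² is computed about the *fitted* line; the identity-line
  variant (residuals about y = x) is also reported as `r_squared_identity`
  since the ideal symmetric slice satisfies y = x, but the OLS value is the
  primary parameter — a deformed slice is characterised jointly by its slope
  away from 1 and its R² below 1. A zero-variance (constant-radius) contour
  is exactly symmetric and returns the convention slope 1, intercept 0,
  R² = 1.
* **Fan areas**: 1° triangles with apex at the centroid, area
  ½ r<sub>i</sub> r<sub>i+1</sub> sin 1°, summed per sector. Star-shapedness
  is enforced upstream, so unsigned and signed sums agree and the full fan
  equals the shoelace polygon area identically. The systematic
  discretisation factor sin 1°/(π/180) ≈ 1 − 5×10⁻⁵ cancels in all area
  *ratios*.
* **Area asymmetry** |LA − RA|/(LA + RA) ∈ [0, 1], for full sides and for the
  backside sectors SP→BRSP and SP→BLSP (anchors at ±separation, default 70°).
* **VB line and Dist<sub>VB</sub>**: the vertebral-body centre is placed
  `sp_offset` anterior of the SP point on the SP–centroid vertical. The
  spinous-process length is not measurable from the surface; the default is
  40 mm, configurable globally and per run, and must stay below the vertical
  diameter. Dist<sub>VB</sub>(offset) is the vertical distance from the VB
  line to the contour point at each grid angle between SP and anchor,
  indexed so the SP sits at offset 0.

Per-level failures (e.g. a slicing plane missing the mesh) become warnings
in the report metadata and the level is omitted; summaries are arithmetic
means over processed levels, with the apex summary over a configured
contiguous level range (absent range → reported as not available, as for a
torso without a localised curve). Apex selection is an operator input — it
cannot be derived from the surface alone.

## Synthetic torsos

The generator emulates the deformity phenotype, not any individual: a
superellipse base (defaults a = 150 mm, b = 100 mm, exponent 2.5 — a
torso-like rounded rectangle), a posterior Gaussian dip (default 8 mm deep,
sd 8°) for the SP groove, and one or more Gaussian rib-hump bumps whose
amplitude follows a Gaussian apex profile across levels (default sd
2 levels). Angles of dip and humps are given as offsets from the posterior
midline, signed towards the right body side. Radial Gaussian noise (preset
default 0.5 mm, roughly the resolution of consumer depth cameras) is drawn
from a per-level stream keyed by (seed, level index), so output is
bit-identical for a fixed seed regardless of generation order. Ground truth
per contour — dip centre, hump side, left/right areas about the point
centroid — is computed by quadrature at 0.01° on the noiseless radius model.
The optional mesh lofts the noiseless surface through ~110 rings plus caps
into a watertight solid (rings are nudged off exact level heights so section
planes cut faces cleanly); detached arm cylinders can be added to exercise
largest-loop selection.

Three presets ship as YAML: `healthy` (dip only), `thoracic_t8` (12 mm
right-sided hump peaking at T8) and `double_t9_l2` (opposed humps at T9 and
L2) — scenario templates for a healthy torso, a single thoracic curve and a
double curve.

What passing tests show — and do not. The synthetic bed establishes the
geometry end to end: exact symmetry nulls, oracle agreement for areas and
R², SP recovery, monotone response to hump amplitude, apex localisation and
mesh round trips. It does not establish clinical validity: real torsos have
non-superellipse waists, breast and scapula asymmetries unrelated to
scoliosis, posture variation between scans, and arm connection artifacts
richer than angular masks. Parameter–Cobb-angle relationships in particular
cannot be inferred from the generator and are out of scope.

## Numerical choices and degenerate inputs

Tolerances: diameter ties and SP ties use 10⁻⁹·*r*<sub>m</sub>; the flat-
minimum flag uses 10⁻³·*r*<sub>m</sub> over > 30°; zero-variance fits switch
to the symmetry convention below 10⁻¹² sum of squares. Contours need ≥ 30
distinct points, must be simple, and aligned radii must be positive with
r(−180°) = r(+180°). Problem sizes throughout (720-point contours, 110×360
mesh, 0.01° quadrature) keep a full 18-level run well under a second while
holding discretisation errors two orders below every test tolerance.

## Known limitations

* Minimum-radius SP detection biases towards the posterior midline on sloped
  baselines and under heavy smoothing (quantified above).
* The VB point is an offset approximation; no vertebral rotation is
  estimated.
* Equal level spacing is an assumption, not anatomy.
* The left-right split axis is the SP–centroid vertical; a strongly rotated
  trunk section violates the implicit assumption that this axis matches the
  anatomical sagittal plane.
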
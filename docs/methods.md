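# Methods

This note documents the models and procedures implemented in `territoria`,
the parameters that matter, and the design choices made where the
construction was genuinely open.

## Virtual territories and simulated trials

A virtual territory is a nested polygon pair: an *outer* region (the
defended area, with known true area) and a *central* area (display/resting
sites), mimicking central-place territoriality where intruders are
intercepted well before they reach the area of concentrated use.  Six stock
outlines span convex (ellipse with 2:1 aspect, equilateral triangle,
circle) to concave (5-point star with inner/outer radius ratio 0.5,
L-shaped "angle" with arm width one third of arm length) to highly concave
(a fixed 12-vertex irregular polygon).  Default true areas are, in
arbitrary units: ellipse 243.58, star 130.09, triangle 88, circle 200.04,
angle 155.63, irregular 395.11.  Each outline is scaled exactly to its true
area; the star, angle and irregular vertex geometries are this package's
own constructions — they reproduce the *shape classes*, not any particular
published outline, so quantitative expectations for concave shapes are
specific to these geometries.

The central area is the outer polygon shrunk to 0.3 of its linear scale
(configurable) about the outer centroid.  When the centroid falls outside
a concave outline (the L-shape), the shrink is anchored at the pole of
inaccessibility instead, which keeps the central area strictly inside.

A full simulated experiment consists of 360 points drawn uniformly over
the central area (rejection sampling from the bounding box, seeded
generator) and 360 edge points placed where rays from the central-area
centroid at 1° bearing intervals (0° = north, clockwise) cross the outer
boundary.  Where a concave boundary is crossed several times the
*outermost* crossing is used — simulated endpoints sit on the outer edge of
the territory — with a "first crossing" option available.  Central and edge
points are paired by a uniform random bijection into 360 trials.
Equiangular subsets of k trials (k any divisor of 360) take every 360/k-th
direction from one of 360/k offsets; over the divisor list
2–360 this gives exactly 810 subsets per territory.

## Estimators

**MCP** is the convex hull.  **Detailed hull (DH)** is a characteristic
(chi-shape) hull: starting from the Delaunay triangulation, the longest
exterior boundary edge is peeled while it exceeds a threshold λ, subject to
a regularity guard (an edge is never removed if the vertex it would expose
is already on the boundary), which keeps the boundary simple and every
point enclosed.  AUTO sets λ to mean + 1 SD of all Delaunay edge lengths.
Ties between equally long edges are broken by the lexicographically smaller
edge midpoint, making the construction deterministic.  DH(λ=∞) equals the
MCP, and on dense convex patterns AUTO leaves nothing to peel, so DH = MCP
there — the property that makes the two estimators agree on convex
territories.  The proprietary GIS "detailed hull" this stands in for uses a
partially disclosed point-selection rule; the chi-shape construction was
chosen because it is open, deterministic, and shares the limiting
behaviour that matters for the benchmark.

**Kernels.**  Fixed bivariate normal KDE with
h_ref = √((s²ₓ+s²ᵧ)/2)·n^(−1/6); GIS plug-ins that advertise the same
selector disagree numerically, so this constant is fixed here and logged.
LSCV minimises the exact closed-form least-squares score over pairwise
distances on [h_ref/20, 2·h_ref] (coarse log-grid, then bounded scalar
minimisation); a minimiser on the interval boundary — the classic LSCV
failure on clumped patterns — returns that boundary value with a failure
flag rather than an error, deliberately surfacing the erratic behaviour
kernels exhibit on the bimodal centre+edge patterns of intrusion trials.
The adaptive mode uses per-point bandwidths hᵢ = h·(f̃(Xᵢ)/g)^(−1/2) with a
fixed pilot at h_ref and g the geometric mean pilot density.  Densities are
evaluated on a 256×256 grid (default) padded by 3.5 bandwidths and expanded
until ≥ 0.99 of the probability mass is enclosed.  Isopleths are
probability-volume contours: cells ranked by density, threshold at the
level enclosing p% of the grid mass, traced by marching squares with
sub-cell interpolation.  For a single point the p%-isopleth area has the
closed form πh²·(−2 ln(1−p/100)), the module's analytic oracle.

**k-LoCoH.**  Each point's local hull is the convex hull of it and its k−1
Euclidean nearest neighbours; hulls are sorted by ascending area and the
p%-isopleth is the union of the smallest hulls covering ⌈p·n/100⌉ points
(a point counts as covered when inside or on a hull).  The 100%-isopleth
exists (union of all hulls) and never exceeds the MCP, with equality at
k = n.  The MSHC rule is automated as: the smallest k whose 100%-isopleth
has no interior holes *and* forms a single connected component.  The manual
field rule rejects topologically unjustified holes **and cutaways**;
without the connectivity requirement, very small k would qualify vacuously
with a scatter of disjoint micro-hulls.  Holes below an area of 1e-12 are
numerical slivers and are ignored.  The automated rule admits no
"biologically justified" exceptions — that judgement cannot be mechanised.

**Stretch-the-centre (STC).**  A fixed kernel at h_ref is fitted to the
calling positions only; isoclines are extracted at the requested levels
(default 1, 5, …, 95, 99).  Each responding trial contributes a correction
link from the crossing of its trial ray with the 99% isocline to its
endpoint; a non-responding trial (the animal claims no ground in that
direction) contributes a link pulling that crossing back to the calling
position.  Every calling position is an identity link.  The links induce a
piecewise-linear transformation: displacements are interpolated
barycentrically over the Delaunay triangulation of the link sources and
extended affinely (nearest triangle) outside it — link sources map exactly
onto their targets and calling positions are fixed points.  All isoclines
are transformed with this one link set, as polylines: warping the density
raster itself is known to produce severe artefacts, so the isocline route
is the designed behaviour, not a shortcut.  The 95% level is the headline
territory estimate.

Two numerical consequences are handled explicitly.  First, the correction
sources are inserted as vertices of the 99% ring before transformation, so
the transformed ring passes through every link target exactly (the raw
transformed ring is exposed as `ring99`).  Second, a strongly non-uniform
displacement field — especially around non-response links, which pull one
ring point all the way back to the centre — can fold the transformed
polyline; self-intersecting results are repaired (buffer-0) with a logged
warning, and isocline nesting is re-checked after transformation with a
relative-overflow tolerance of 1% of the inner isopleth's area (isopleths
are raster-derived, so hairline overlaps below that are discretization
noise).  Genuine violations are reported, never silently accepted.

## Evaluation machinery

Percent of true area is 100·Â/A, rounded to integer percent in table
output (raw values retained).  Accumulation tables evaluate an estimator
over *all* equiangular offsets for each k (exhaustive, not sampled) and
report mean and SD; polygon estimators (MCP, DH, LoCoH) are evaluated at
full extension, parametric kernels at their 95% isoclines.  Rank stability
is the smallest k from which the ordering of units by area equals the
ordering at the largest k, ties broken by unit id.  Stepwise change is the
percent change of the mean between consecutive k, with the last step
exceeding a threshold (default 2%) flagged.  Isopleth coverage reports the
smallest level whose area reaches a reference hull's area and the smallest
level fully containing it; containment is stricter, so the second is never
below the first.

## Synthetic field cohort

`generate_fixture_individuals` emulates a cohort of territory holders for
pipeline tests: non-overlapping elliptical territories of varied size
(60–420 area units), aspect (1–2) and orientation inside an arena; 15
calling positions per individual in the central area; 12 trials at every
30° in the semi-random field order (first direction random, then +180°,
then +90°/+270° in random order, repeated over the remaining two
"crosses"); trial endpoints on the outer boundary along the trial
direction; independent non-response probability of 4% per trial, the order
of magnitude observed in playback fieldwork (a handful of missing
endpoints among ~180 trials).  What it does *not* emulate: movement paths,
detection/response physiology, observer mapping error, temporal
autocorrelation, and real territory shapes.  Tests passing on this cohort
therefore validate the geometry and bookkeeping of the pipeline, not
field-data performance.

## Problem sizes and benchmark conditions

The simulation benchmark uses the full design (360 trials, all 810 subsets
per territory, six territories, one logged seed).  The LoCoH/MSHC scan on
a 720-point pattern walks k upward from 3 and typically settles near
k ≈ 90 on the circle; the scan is the dominant cost of the benchmark
(~15 s).  The synthetic cohort uses 15 individuals, matching the scale of
a realistic field campaign.

## Known limitations

- The detailed hull is a chi-shape, not a reimplementation of any
  proprietary hull; absolute percentages on concave shapes depend on both
  λ and the shape geometry.
- With this package's own star and angle geometries, the mean DH rank
  order of the six stock territories settles at 15 equiangular trials (the
  star and angle accumulation curves cross between 12 and 15): the
  two shapes' asymptotic areas are close and their concavity penalties at
  small k differ.  Rank stability from ~10–12 trials should be expected
  only for territory sets whose areas are better separated; the result is
  geometry-dependent, not a property of the estimator alone.
- LSCV bandwidths on intrusion-trial patterns are frequently boundary
  failures by construction; they are reported, not repaired.
- The MSHC automation scans k linearly; hole-freeness is not monotone in
  k, so no bisection shortcut is taken.
- The rubbersheet transformation is not guaranteed injective; folded
  isoclines are repaired and flagged, and the repaired polygon can clip a
  spike that the raw transformed ring (`ring99`) retains.
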
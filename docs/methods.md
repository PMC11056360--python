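# Methods

`brimplan` implements a geometric planning pipeline for extra-articular screw
placement along the pelvic brim through the Stoppa (anterior intrapelvic)
window. The hip joint surface is not visible through that window, so screws
drilled into the brim can inadvertently enter the acetabular socket. The
pipeline turns that risk into arc-length arithmetic on the brim curve.

## Model and landmark construction

A hemi-pelvis is reduced to three structures: the brim ridge as an ordered
3-D polyline from the sacroiliac joint (point **C**) to the pubic symphysis
(point **D**), the acetabular rim point set, and the cranial body-axis unit
vector. All lengths are in millimetres; arc positions are cumulative chord
length from the sacroiliac end.

Two constructed landmarks split the brim into zones:

* **Point A** — the brim is intersected with the transverse plane
  (perpendicular to the body axis) through the *superior* acetabular margin,
  i.e. the rim point with maximal body-axis projection. On anatomic brims
  the crossing is unique; if a pathological curve yields several, the one
  closest to the acetabular center is taken.
* **Point B** — the brim is treated as a portion of a circle, fitted by
  total-least-squares plane projection, a Kåsa algebraic fit and geometric
  Gauss–Newton refinement (convergence when the center/radius update falls
  below 1e-9 mm, at most 100 iterations; non-convergence raises an error
  carrying the last iterate). The ray from the fitted circle center through
  the *inferior* acetabular margin is intersected with the brim by nearest
  approach within a 2.0 mm capture radius — a 3-D ray generically misses a
  polyline, and the capture radius restores the on-surface intersection
  semantics of the original construction on a discretized curve.

Zone lengths are then **a** = C→A, **b** = A→B (the dangerous zone over the
socket) and **c** = B→D, measured along the brim after resampling at 0.2 mm.
The chordal error of that resolution on a 44 mm-radius arc is ~1e-6
relative, far below the 0.5 mm recovery contract; halving the spacing
changes measured zones by well under 0.05 mm.

Numerical conventions: absolute tolerances in mm throughout (the anatomy is
fixed at the 1e2 mm scale); vertices within 1e-9 mm of a plane count as
lying on it; distance ties in nearest-point queries resolve to the smaller
arc position; fitted normals are signed to have a non-negative cranial
component (ties toward +x, then +y). Zone measurement is invariant under
rigid motions of the whole model to ≤1e-6 mm, and equivariant under
scaling when the resampling spacing is scaled with the model (with a fixed
absolute spacing, discretization error of order 1e-4 mm breaks strict
scale equivariance — the spacing is a resolution parameter, not anatomy).

## Screw-placement arithmetic

With adjacent-hole spacing *d* of a reconstruction plate:

* the number of screws that fit a safe zone is the largest *n* with
  *n·d* ≤ zone length (equality counts as safe);
* the number of vacant holes over zone b is the smallest *n* whose span
  *e_n* across *n* consecutive empty holes satisfies *e_n* ≥ *b*.

The built-in plate catalogue holds four manufacturers' measured rows of
(*d*, *e₁…e₄*) plus a column-mean row; means are computed in exact decimal
arithmetic and rounded half-up to 2 decimals (12.225 → 12.23), the
convention used for every reported mean in the package. The catalogue does
not define how *e_n* relates to *d*; the affine model *e_n* = (*n*+1)·*d* − *h*
fits all rows with residuals ≤ 0.35 mm, *h* ≈ 4.9–5.4 mm (close to a hole
diameter), and extends spans beyond *n* = 4 with a default *h* = 5.1 mm.
Tabulated values always take precedence; extrapolated spans are flagged.

For the reference anatomy (zone means ≈ 41/41/57 mm) and the mean plate
(*d* = 12.23 mm) this yields the 3/3/4 rule: 3 screws in zone a, 3 vacant
holes over zone b, 4 screws in zone c. In the symphysis-referenced frame
the safe bands are [0, c] and [c+b, a+b+c] — with mean anatomy roughly
0–6 cm and 10–14 cm from the symphysis, the 6–10 cm band being off limits.

A brim fracture line inside zone b anchors a *reference hole* (the plate
hole nearest the fracture), which is never drilled. Zone b is divided into
equal thirds, boundaries belonging to the more superior third. Offsets are
counted positive toward the symphysis (*distal*): a superior-third fracture
skips offsets {0, +1, +2}, middle {−1, 0, +1}, inferior {−2, −1, 0}. This
replaces the blanket skip-all-of-zone-b rule; because three skipped holes
span *e₂* < *b*, a fracture-referenced plan may drill zone-b holes — these
are explicitly flagged in the hole schedule, and the unconditional
no-drilling-in-(c, c+b) guarantee is asserted (and tested) only for plans
without fracture information. Hole centers decide zone membership; a center
exactly on a zone boundary counts as safe. Drilled-per-zone counts are
validated against the *n·d* ≤ zone bound; a violated bound (possible when
hole centers sit exactly on both boundaries of a zone) is recorded as a
plan warning rather than an error.

## Synthetic pelvis generator

The CT cohort behind the reference tables is not publicly deposited, so
validation runs on parametrically generated hemi-pelves with *known* ground
truth, constructed inversely from target zone lengths:

* The brim is an arc of a circle (default radius 44 mm, so a ~139 mm brim
  spans roughly a half circle) in a plane inclined 60° from the transverse
  plane, mimicking pelvic-inlet inclination. The arc is sampled as an
  equal-chord polyline per zone (≈0.5 mm chords) so the cumulative chord
  positions of the landmark vertices equal a, a+b and a+b+c *exactly* —
  the ground-truth identities hold to 1e-6 mm rather than being limited by
  chordal shortening.
* The inferior acetabular rim point lies on the center→B ray at 1.15× the
  brim radius (the socket sits lateral to the inlet; the exact factor is
  configurable because no anatomic value is fixed by the zone lengths).
  The superior rim point sits 10 mm lateral to brim point A at exactly A's
  cranial height. The rim circle takes these two points as a diameter pair
  with its second in-plane basis vector horizontal, making them the unique
  cranial/caudal extremes of the rim point set; the socket sphere sits on
  the rim-circle axis. The nominal socket radius (default 24 mm) is a
  floor — extreme zone-target combinations widen the margin chord beyond
  an anatomic socket, and the sphere then grows to keep the rim on it.
* Measurement noise is a smooth correlated field, not white noise:
  Gaussian control points roughly every 15 mm along the curve,
  cubic-spline interpolated, per-point norm clipped at 3 sd. This emulates
  segmentation/reconstruction error of a CT-derived surface. Independent
  per-vertex noise at sub-millimetre vertex spacing would inflate chordal
  arc length catastrophically (a ~0.3 mm white-noise field adds ~80% of
  length at 0.5 mm spacing) and corresponds to no physical imaging error.
  Consequently the generator does *not* probe robustness to voxel-level
  speckle, sampling irregularity, or real anatomic departures from the
  circular-brim idealization — passing tests show the pipeline's geometric
  constructions are correct and stable under smooth model error, not that
  the circle model fits every patient.

Cohorts mirror the four reference groups (male/female × left/right, sizes
28/17/20/15) with per-subject zone triples drawn from per-group normal
distributions truncated at ±3 SD (redraw on violation; truncation bias is
negligible at the reference SD/mean ratios). All randomness flows from
explicit integer seeds; there is no global random state.

## Statistics

Group summaries report mean ± SD (n−1 denominator) per zone and for the
total brim, rounded half-up to 2 decimals for display with unrounded values
retained. Two-sample comparisons use Student's pooled-variance t by default
(Welch behind a flag, since sides/sexes may differ in variance); multi-group
comparison is classical one-way ANOVA. Subjects contribute one hemi-pelvis
each, so all tests are unpaired. Calibration is verified by simulation:
across 500 null cohorts (all groups drawn from one distribution) the ANOVA
rejects at α = 0.05 in 5% ± 2% of replicates, and the two-group F equals t²
to 1e-9 relative. The reference tables' own P-values are not reproducible
targets — they depend on the unavailable per-patient data — and are not
asserted anywhere.

## Problem sizes and defaults

Default problem sizes used by the test suite and the acceptance script:
200 noise-free pelves (targets uniform in [30, 70] mm per zone) for the
0.5 mm recovery bound; 50 pelves at noise sd 0.3 mm for the 1.5 mm median
bound; 1,000 random plate placements for the safety property; 500 null
cohorts for ANOVA calibration; 50 pelves in the acceptance script's
recovery metric. These sizes make every stochastic check stable across
seeds while keeping a full run in seconds.

## Known limitations

* The brim-as-circle model and the planar brim arc are idealizations; real
  brims deviate, and the package measures whatever polyline it is given —
  garbage ridge extraction in, garbage zones out. Ridge extraction from
  raw surface meshes is out of scope.
* The distance along the brim is measured on the 1-D ridge curve; a
  measurement that followed the triangulated bone surface could differ
  slightly on strongly curved specimens.
* Whether the point-B construction should live in the projected
  inlet-obturator view (2-D) or in 3-D is ambiguous in the source
  construction; this package works in 3-D and absorbs the out-of-plane
  component with the 2 mm capture radius.
* Screw trajectory angulation, fluoroscopy simulation and biomechanical
  stability are out of scope; the plan is pure arc-length arithmetic.
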
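# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `femurdisp`, and what the synthetic phantoms do
and do not establish about real data.

## Measurement model

The object of measurement is the rigid motion of the femoral head
fragment in a nominally undisplaced femoral neck fracture, expressed
relative to the patient's own intact contralateral femur.  The
contralateral side serves as the subject-specific template: reflecting
the fractured-side surface across the sagittal plane and rigidly aligning
it to the healthy side would, for a perfectly symmetric and unfractured
pair, produce an exact overlap.  Any residual misfit of the head is then
attributed to the fracture and summarized by three parameters:

- `d1` (mm): distance between the femoral head centers after
  superimposition;
- `d2` (mm): distance between the deepest points of the fovea capitis;
- `α` (degrees, in [0, 180]): angle between the two center→fovea lines,
  treated as *directed* lines.  Directed lines (rather than axial lines
  folded to [0, 90°]) are used because fragment rotations well above 45°
  are clinically meaningful and must not alias.

Assumptions: left–right skeletal symmetry (violations enter `d1/d2/α`
directly as error); millimetre units throughout (surface formats carry no
unit metadata); a patient-like, right-handed coordinate frame in which
the sagittal mirror plane defaults to `x = 0` (overridable per run, since
exported meshes may live in scanner or segmentation-tool frames).

### Superimposition

Registration is nearest-vertex ICP on the union of the shaft and neck
regions.  Excluding the head region is essential, not cosmetic: the head
fragment is exactly the part whose displacement is being measured, and
letting it participate would bias the alignment toward cancelling that
displacement.  Details:

- Initialization: centroid alignment plus principal-axes alignment of the
  selected regions.  The eigenvector sign ambiguity leaves four proper
  rotations; the candidate with the lowest nearest-neighbour RMS wins,
  with ties broken toward the rotation closest to the identity.  This
  makes the result deterministic and, because the initialization is
  computed from the point sets themselves, the whole pipeline is
  equivariant under a common rigid motion of both inputs (verified to
  ~1e-12 relative in the tests).
- Per-iteration transform: Kabsch (SVD) on the current correspondences.
- Convergence: change in RMS correspondence distance below 1e-6 mm, or
  200 iterations; a final RMS above a sanity bound (default 10 mm) emits
  a warning and clears the `converged` flag rather than raising.
- Options: a trimmed fraction (default 1.0, configurable down to 0.8)
  discards the worst pairs each iteration, guarding against fracture-gap
  outliers; `max_points` takes a seeded, deterministic subsample of the
  source vertices for large meshes (used by the cohort simulator; the
  single-pair default keeps all points).

Point-to-point correspondence was chosen over point-to-plane for
simplicity; at the vertex densities the pipeline targets (~1–3 mm edge
length) the accuracy reserve against the acceptance tolerances is two to
four orders of magnitude.

### Head center: the close-fit sphere

The head center is the center of a least-squares sphere fitted to the
head-region vertices: an algebraic linear fit (solving
`|p|² = 2c·p + (r² − |c|²)`) initializes a geometric refinement that
minimizes `Σ(‖p − c‖ − r)²` with Levenberg–Marquardt.  The refinement
result is kept only if it does not increase the RMS radial residual, so
the report is never worse than its initializer.  Near-coplanar inputs
(condition number above 1e10) raise a degenerate-geometry error rather
than returning an arbitrary sphere.

The fovea pit is a systematic inward deviation from sphericity, so the
default fit is robust: points with inward radial deficit
`r − ‖p − c‖ > 0.5 mm` are excluded and the sphere refitted, up to 5
passes or until the exclusion set stabilizes.  On phantoms with a 3 mm
pit this recovers the true radius to well under 0.01 mm where the plain
fit is ~0.1 mm biased.

### Fovea localization

Given the fitted sphere, the deepest fovea point is the head vertex of
maximal inward deficit, provided that deficit exceeds a detection
threshold (default 1.0 mm — comfortably above surface noise, comfortably
below anatomical pit depths of 2–5 mm).  Ties are broken by
lexicographically smallest coordinates for determinism.  If no vertex
passes the threshold the operation fails explicitly; callers may supply a
manual landmark instead.  Manual landmarks for the fractured side are
specified in its original (unmirrored) frame and transported through the
same mirror + registration map as the mesh, mirroring how a reader would
pick points on the reconstructed model.

### Observability limit

`α` measures the rotation of one line.  A rotation of the head fragment
*about* the center→fovea axis leaves that line fixed and is therefore
invisible to `α`; the test suite asserts this as a property.  The measure
is likewise insensitive to the component of rotation parallel to the
line; cohort simulations therefore draw rotation axes perpendicular to
the center→fovea direction, i.e. they simulate the component the measure
is defined to capture.

## Statistics

- **Fleiss' kappa** for m-rater categorical agreement and **Cohen's
  weighted kappa** (linear or quadratic weights) for two-occasion
  intra-rater data; both delegate to `statsmodels` and are reported with
  the **Landis–Koch** verbal band (<0 none; ≤0.2 slight; ≤0.4 fair; ≤0.6
  moderate; ≤0.8 substantial; ≤1.0 almost perfect — band boundaries
  belong to the lower band).  A chance-agreement denominator of zero
  (all ratings in one category) raises an undefined-kappa error.
  Continuous landmark picks are discretized for these statistics by an
  agree/disagree rule against a per-subject reference point with a
  configurable tolerance radius (default 2 mm).
- **Mann–Whitney U** (two-sided) compares displacement parameters between
  two groups, via `scipy`: the exact null distribution when the pooled
  sample has ≤12 tie-free observations (or on request), otherwise the
  normal approximation with tie and continuity corrections.  The exact
  path is cross-checked in the tests against an independent
  full-enumeration oracle over all rank assignments.

## Synthetic phantoms

A phantom femur is assembled from three primitives: an icosphere head of
radius 22 mm carrying a cosine-profile fovea pit (footprint radius 5 mm,
depth 3 mm, tessellation rotated so one vertex sits exactly at the pit
bottom), a neck cylinder (radius 14 mm, length 35 mm) and a shaft
cylinder (radius 15 mm, length 120 mm), joined at a 130° neck-shaft angle
with 12° anteversion — plausible adult proportions.  The fractured side
is the exact mirror image of the healthy side (true contralateral
symmetry) with the spec's rigid `fragment_transform` applied to
head-region vertices about the mirrored head center, leaving a subcapital
fracture-plane discontinuity; no bone-overlap resolution is attempted,
since landmark-level measurement does not need it.  Independent isotropic
Gaussian vertex noise (default SD 0.05 mm) is added per side.  Generation
is bit-deterministic given the seed.

Ground truth emitted with every phantom: the applied transform, both
landmark sets, the implied head-center displacement magnitude (what `d1`
should read) and the implied line-rotation angle (what `α` should read).

What the phantoms do **not** emulate: real cortical-surface texture,
osteophytes or segmentation artefacts; genuine anatomical left–right
asymmetry (only isotropic noise); fracture comminution or impaction along
a realistic fracture plane; and any particular CT reconstruction or
smoothing.  Passing phantom tests therefore establishes the correctness
and numerical stability of the *measurement machinery* under known rigid
displacements — not the clinical accuracy of the method on patient CT,
which would require imaging data.

### Cohort simulation

Simulated studies draw per-subject fragment displacements from
folded-normal magnitude distributions (magnitudes are non-negative and
group effects are conventionally reported as mean ± SD), with translation
directions uniform on the sphere and rotation axes uniform perpendicular
to the center→fovea line.  The default two-group cohort mirrors the
incomplete-vs-complete (Garden Ia vs II) contrast, with group sizes 15
and 60 and (translation mean, SD; rotation mean, SD) of (3.69 mm,
1.77 mm; 4.91°, 2.49°) and (7.16 mm, 4.58 mm; 18.77°, 9.10°)
respectively.  Each subject runs through the complete pipeline; the
cohort phantom template uses a 3.5 mm mesh resolution and a 1000-point
ICP subsample, sizes at which per-subject measurement error (~0.1–0.2°,
~0.05 mm) is negligible against millimetre/degree-scale group effects
while a 75-subject cohort simulates in about 1.5 s.  The single-pair
default resolution is 1.5 mm.

Monte-Carlo checks in the acceptance layer: with two groups drawn from
identical distributions (n = 30 each, 20 replicate cohorts) the α
comparison rejects at close to the nominal 5% rate; with rotation means
separated by one pooled SD it rejects in ≥80% of replicates.

## Numerical conventions and edge cases

- Degenerate inputs raise typed errors: <4 or near-coplanar points for
  sphere fitting, empty region selections for ICP, zero-length segments
  for angles, missing fovea above threshold, undefined kappa, empty
  samples for the U test.
- The mirror operation reverses face winding so outward normals survive;
  applied twice it reproduces the input to 1e-12.
- STL files are triangle soups; on read, exactly duplicated vertices are
  merged deterministically in first-occurrence order.  Per-vertex region
  masks are keyed to vertex order, so the indexed formats (PLY/OBJ) are
  preferred for mask-bearing interchange and are what the CLI writes.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit spec/CLI seeds; derived seeds stay below 2³¹.
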
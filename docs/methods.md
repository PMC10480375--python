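# Methods

## Problem setting

Intraoral scanners export STL surface meshes in millimetres with reliable
geometry but unreliable facet normals, duplicated per-facet vertices, no
topology, and no common reference frame between scans. The package
measures the volume enclosed between a baseline ridge scan and a
post-augmentation scan of the same anatomy. All internal arithmetic is in
mm/mm³; cm³ appears only at reporting (÷1000).

## Mesh model and validation

Meshes are held as indexed vertex/face `trimesh.Trimesh` objects.
Validation merges duplicate vertices on a configurable snap grid (default
1e-6 mm — STL writers duplicate every vertex per facet and the scanner's
export precision is unspecified, so the tolerance is a parameter rather
than a constant), drops faces with repeated indices, near-zero area
(< 1e-12 mm²) or duplicated vertex sets, and recomputes normals from
winding order, made globally consistent and outward for watertight
components. Stored STL normals are never trusted. Watertightness is
defined strictly: every undirected edge incident to exactly two faces.
One subtlety: a zero-area face is removed only if one of its edges is
unshared. Cap triangulations necessarily contain slivers along collinear
rim runs, and float32 STL round-trips can collapse their area to zero;
removing such a closure-preserving sliver would open the solid
(a T-junction), while keeping it costs nothing — it contributes no
volume. Dangling zero-area facets (scanner junk) are still dropped.

## Registration

Coarse alignment uses three corresponding landmark points per scan
(non-collinearity enforced by triangle area > 1e-9·scale²). Refinement is
point-to-point weighted ICP: the Kabsch/SVD solution is the closed-form
optimum for point-to-point correspondences, which is why that variant is
used rather than point-to-plane. Correspondences go from (a deterministic
even-stride subsample of) the weighted moving vertices to the closest
point on the fixed *surface* — candidate faces from a face-centroid
KD-tree (k = 8) plus the faces around the nearest fixed vertex, then exact
point–triangle projection — because the two scans tessellate the anatomy
differently.

Stopping rule: weighted-RMS change < 1e-7 mm or 600 iterations;
correspondences beyond 5 mm are dropped; at most 1000 moving points are
used. Point-to-point ICP converges only linearly along weakly constrained
sliding directions of a ridge-like surface, so the iteration budget is
deliberately large and cheap iterations (small subsample) are preferred
over few expensive ones; with these defaults a 5° / 2 mm synthetic offset
is recovered to ≪0.1° / 0.05 mm in a few seconds. Weight maps are
continuous in [0, 1]; weight-0 vertices never enter the computation, so
they are provably inert. A final weighted RMS above 0.5 mm raises a
registration-quality error — the numeric replacement for visual
confirmation of the match.

## Solidification

The scans are cropped (faces whose three vertices lie in an axis-aligned
box around the ROI) so that exactly one open boundary loop remains; loops
are found by chaining edges with single face incidence, and non-manifold
boundary junctions are rejected. The closing direction defaults to the
negated area-weighted mean patch normal — the only well-defined global
"away from the surface" direction for a ridge-shaped patch — and the same
direction (computed from the baseline crop) is reused for the augmented
crop so that the added closure geometry cancels in the subtraction.

Two closure modes exist. `translate` extrudes the rim rigidly by the
depth and caps the displaced (generally non-planar) loop with a membrane
triangulated in the projection plane. `plane`, the pipeline default,
extrudes every rim vertex onto a plane perpendicular to the closing
direction at `depth` below the deepest rim point, giving a planar cap that
cannot poke back through a strongly curved crop. For planar patches the
two are identical (prism law A·depth, tested); for the measured difference
the choice is immaterial because baseline and augmented closures cancel —
an invariance the acceptance suite checks by varying the depth over
{3, 5, 10} mm (default 6 mm; it only has to exceed the registration
residual scale). Cap triangulation is deterministic O(n²) ear clipping;
self-intersecting rims are rejected rather than repaired, so a scan whose
margin clips the graft fails loudly instead of yielding a quietly wrong
volume.

## Boolean engines

No robust mesh-Boolean library is a dependency; the package carries two
engines behind one interface, selected automatically:

* **Exact half-space clipping** whenever one operand is convex — which
  covers every ROI intersection (box or convex ROI solids) and the
  analytic unit tests. A clip splits crossing triangles in the plane and
  caps the cut loops by ear clipping; a convex-subtrahend difference is
  decomposed into disjoint clipped pieces (one per subtrahend plane),
  returned without vertex sharing so each piece stays individually
  watertight. Exact up to floating point.
* **Voxel occupancy algebra** for the general case, in particular
  augmented-minus-baseline. Both solids are rasterised on a *shared* grid
  (default pitch 0.1 mm) by vertical-column scanline parity — each
  triangle contributes plane crossings to the grid columns its footprint
  covers; voxel centres between successive sorted crossings are inside.
  Large-footprint sliver triangles (caps) are rasterised by exact per-
  column intervals to avoid bounding-box blowup. The grid origin carries a
  fixed irrational sub-voxel offset so geometry never coincides exactly
  with sample planes. Set algebra happens on the occupancy arrays, so
  coincident far-field surfaces (the un-grafted part of both scans and the
  identical closures) cancel exactly at grid level; the result is remeshed
  by marching cubes at level 0.5. On the solids handled here the remeshed
  volume is within ≈0.1 % of truth at 0.1 mm pitch; the tests also compare
  it against an independent oblique-ray parity oracle and analytic
  lens/clip volumes.

The dual-ROI scale factor defaults to s = 0.98 (inner ROI 2 % smaller
about the ROI centroid): small enough to stay close to the outer box,
large enough to exceed mesh-thickness and registration-residual scales.
The measured volume is invariant to s ∈ {0.95, 0.98, 0.99} (tested)
provided the graft lies strictly inside the inner ROI. Fragment filtering
keeps the largest face-adjacency component by default (ties broken by the
lexicographically smallest minimum vertex), with a threshold policy for
particulate grafts that legitimately split into several attached pieces.

## Volume

Divergence-theorem volume per connected component, orientation-normalised
and summed as absolute values, so a stray inverted component of a noisy
Boolean output cannot cancel volume. The slice oracle mirrors the manual
gold standard: mid-slice planes every 0.25 mm (thickness configurable,
axis defaulting to the longest bounding-box extent), cross-section area by
the even-odd rule — section loops are grouped by nesting depth with
shapely so holes subtract — and volume = Σ area × thickness. It is exact
for prisms sliced along their axis and converges to the divergence volume
as the thickness shrinks; agreement within 1 % on every measured
difference solid is the geometric form of the manual/semiautomatic
equivalence claim.

## Statistics

* **TOST** on paired differences, margin ±0.15 cm³, α = 0.05: one-sided
  t-tests against each bound, `tost_p` = max of the two, equivalence ⇔
  tost_p < α ⇔ the 90 % CI lies inside the margin (a property the tests
  check over 1000 random data sets). The ordinary paired t-test is
  reported alongside; both 90 % and 95 % CIs are returned, labelled.
  Zero-variance differences yield a width-0 CI and a decision by the mean.
* **ICC(A,1)**: two-way ANOVA decomposition, absolute-agreement
  single-measure form with the McGraw–Wong F-based 95 % CI; consistency
  ICC(C,1) behind a flag. Absolute agreement is the default because the
  design is test–retest of the same quantity by the same rater.
  Interpretation bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
  ≥ 0.9 excellent. The implementation is cross-checked against an
  explicit-loop ANOVA oracle (1e-10) and pingouin in the tests.
* **Wilcoxon signed-rank**, implemented as the paired one-sample test on
  differences (the data are paired): zeros dropped and counted, ties
  mid-ranked, exact distribution for n ≤ 25 (full 2ⁿ enumeration when
  ties block the standard recursion, n ≤ 12), normal approximation with
  continuity correction beyond.
* Missing pairs are excluded and counted (complete-case analysis).

## Phantom generator

The baseline is a height field z(x, y): a logistic ridge profile (crest
height 12 mm, half-width 5 mm, slope 2 mm) plus a long-wave modulation and
six seeded low-amplitude sinusoids (0.15 mm), tessellated on a 0.25 mm
grid over 30 × 40 mm — scanner-like density. Augmentations add a
technique-specific height field: a smoothstep-edged plateau (block B), a
wider flat plate with granular Gaussian-bump texture (split block S1), a
cosine-arched shell with texture (S2), or an exact hemisphere for
closed-form truth. The added field is rescaled so its integral hits a
target volume; study targets are drawn per technique around 0.35 ± 0.085,
0.76 ± 0.15 and 0.82 ± 0.17 cm³ — the volume scales typical of these
three grafting techniques — so the statistics run in the regime that
matters.

Ground truth is the 2D midpoint-rule integral of the analytic added field
on a 0.02 mm grid (or the closed form), computed by machinery disjoint
from the measurement pipeline. The augmented scan is emitted under a known
random rigid pose (≈5°, ≤3 mm), with independent per-scan vertex noise
along normals, 0.05 mm landmark pick error, a weight map that zeroes the
dilated graft footprint, and optional floating icosphere fragments 1–2 mm
above the graft. Within one generated study all techniques of a specimen
share the same baseline anatomy (a separate anatomy seed), as the physical
protocol implies.

What the phantoms do **not** model: real mandible shape, correlated
scanner noise, specular/moisture artefacts, partially attached graft
particles, or soft-tissue motion. Passing tests therefore demonstrate the
correctness of the geometry and statistics chain under controlled
conditions, not field performance on clinical scans.

Re-measurement variability between the two reading sessions (t0/t1) —
which in interactive workflows comes from the human operator — is
emulated by re-running with an ROI placement jittered by N(0, 0.3 mm) per
axis and an ICP initialisation perturbed by ≈0.5° / 0.2 mm.

## Problem sizes and numerical choices

Default phantom meshes carry ≈19 500 vertices; the test suite uses 1–3
specimens per study and the acceptance script 4, with voxel pitch 0.1 mm —
sizes chosen to keep a full run in minutes on one core while leaving every
tolerance comfortably met. Tolerances: vertex merge 1e-6 mm, rotation
orthonormality 1e-9 (enforced at 1e-6 on input), ICP RMS-change 1e-7 mm,
degenerate-face area 1e-12 mm², Boolean grid pitch 0.1 mm, ROI scale 0.98,
closure depth 6 mm. Degenerate inputs fail with typed errors
(collinear landmarks, rank-deficient Kabsch covariance, non-manifold
boundaries, multi-loop patches, open meshes at volume time, empty crops or
differences, ROI beyond the scan margin); pipeline drivers convert them to
structured per-scan failure records and continue with the remaining scans.

## Known limitations

* The voxel engine's accuracy is resolution-bound; coherently quantised
  flat axis-aligned faces of *tiny* solids (≲1 mm) can see percent-level
  marching-cubes error, which is why analytic unit fixtures route through
  the exact engine. Pipeline-scale solids are curved and well above the
  pitch, where errors average out.
* Exact clipping rejects cross-sections with holes (nested cut loops) and
  falls back to the voxel engine rather than bridging holes in the cap.
* Point-to-point ICP assumes the three-point initialisation is within the
  correspondence capture range (a few mm); there is no global
  initialisation-free registration.
* The slice oracle's runtime grows with mesh size × slice count; it is a
  validation tool, not the primary measurement.
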
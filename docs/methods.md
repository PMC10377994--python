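# Methods

This note records the model, the conventions, and the design choices made
where the underlying measurement system left the construction open.

## Coordinate frame and landmark schema

All geometry lives in LPS (left–posterior–superior) millimetres; Slicer
FCSV files, which are commonly RAS, are converted on read using the file's
`CoordinateSystem` header (RAS↔LPS is a sign flip of the first two axes and
its own inverse). A single canonical frame removes sign ambiguity from
every downstream projection. Units are fixed to millimetres; there is no
unit autodetection.

The registry holds 126 unique landmark names in five regions (cranial 28,
mandibular 25, teeth 20, soft tissue 48, airway 6); bilateral entries are
expanded to `_L`/`_R` pairs, and the posterior nasal spine `alv(PNS)`
belongs to both the cranial and airway regions, so the per-region counts
sum to 127. Name matching on load is exact after whitespace trimming plus
an explicit, user-supplied alias table — never fuzzy. Sessions may be
incomplete: each parameter declares the landmarks it needs and evaluates to
a missing marker (with a reason) rather than failing a batch.

One registry entry deserves a flag: the soft-tissue point `sbal'`
(Subalare) carries the definition text "most inferior point of the
earlobe", which contradicts its anatomical name and its usual placement at
the nasal alar base. The registry stores the schema text verbatim; the
point feeds no measurement parameter, so the discrepancy has no
computational effect.

## Reference planes

FH is fitted to the four orbitale/porion points by ordinary least squares
with the superior coordinate as the response — the plane is near-horizontal,
so vertical residuals are well conditioned. An orthogonal
(total-least-squares) fit is available as `fit_plane_tls` for comparison,
but OLS is the default and the documented behaviour. SP passes through
nasion and basion perpendicular to FH; HP through nasion parallel to FH;
CP through nasion perpendicular to both; MP is the exact plane through
gnathion and the two gonions; TVL passes through subnasale perpendicular to
FH and SP.

Normal orientations are anatomical, hence invariant under any rigid
placement of the scan: FH/HP/MP/OP normals point superior (the nasion side
of gnathion), the SP normal toward the anatomical left (the `_L` porion),
CP/TVL normals anterior (nasion relative to basion). These orientations fix
the signs of all signed quantities below.

The occlusal plane's printed construction ("through u1d, u1m and u6 of both
sides and the midpoint of left and right") is ambiguous. Two readings are
implemented behind `op_mode`: `midpoint3` (default) takes the exact plane
through the four-point incisal-edge midpoint and the two first-molar cusps;
`ols6` least-squares-fits all six tooth points. Neither reading is claimed
to be the original authors'.

## Measurement conventions

* Three-point angles are projected onto the named plane first, then
  measured in [0°, 180°]; line–line and line–plane angles (the plane
  replaced by its intersection line with the projection plane) lie in
  [0°, 90°].
* The facial-convexity angle g'-sn'-pg' reports the supplementary angle
  whenever the raw angle is obtuse, so the reported value is acute.
* Canting angles are signed: positive when the left point of the bilateral
  pair is superior after coronal projection. Maxillary yawing is signed:
  positive when the anterior end (ANS) deviates to the left after axial
  projection. A mirror-symmetric head gives exactly zero for all of them,
  and the magnitudes agree with the unsigned printed definitions.
* Condyle yaw (per side) had no stated sign convention; the implemented
  one measures the axial angle of the condylar medio-lateral axis from the
  pure lateral direction of its side, positive when the lateral pole sits
  anterior to the medial pole. Under a midsagittal mirror the left and
  right condylar yaws exchange values (the side-specific analogue of the
  sign flip of midline yaw).
* Midline "distance to SP" parameters (Pg-SP, U1-SP, L1-SP, pg'-SP) are
  absolute; profile distances to the TVL are signed, anterior positive
  (protrusion/retrusion carry opposite signs in profile analysis).
* "Difference in distance" rows are signed differences of signed plane
  distances: positive overbite = upper incisal edge inferior to the lower
  (vertical overlap); positive overjet = upper edge anterior; U1 exposure,
  lower-third height and facial height are superior-minus-inferior.
* Incisor axes run from the incisal-edge midpoint (the centroid of the
  four distal/mesial edge points) to the midpoint of the two root apices,
  upper and lower alike. ANB defaults to the unsigned three-point angle;
  `anb_signed` switches to SNA − SNB.

The evaluator is data-driven: all 78 rows are declarative entries binding
landmark names and plane labels to small formula closures over the
geometric kernel, so invariance suites iterate the registry generically and
every definition is auditable in one place.

## Airway

Cross-sectional areas are planar mesh sections: all closed intersection
loops are summed by the shoelace formula — the pharyngeal lumen may be
non-convex or bifid at a slice, and disjoint loops are genuinely airway.
An intersection contour that fails to close (a mesh boundary crossing the
plane) raises an error naming the defect; areas require closed loops but
not global watertightness. The slice grid is anchored at the `alv(PNS)`
plane, descends in 1 mm steps (configurable) and includes both bounding
planes, appending the exact bottom plane when the gap is not a step
multiple. The minimum area is searched on that same grid.

Volumes are exact volumes of the watertight mesh clipped between two
parallel planes. Rather than triangulating cap polygons, the implementation
applies the divergence theorem with the field F = (x·u)u, div F = 1, where
u is a unit vector parallel to both clipping planes: the planar caps then
carry zero flux and only the clipped lateral triangles are integrated
(exactly, since the integrand is linear per facet). Trapezoidal integration
of a 0.1 mm slice profile is kept in the test suite as an independent
oracle; the two routes agree to well under 1% on all phantoms. Non-watertight
meshes are refused for volumes with a repair hint. The velopharynx/
glossopharynx split at the uvula plane partitions the total airway volume
exactly (to floating-point).

"Mean area" defaults to the mean of the 1 mm slice profile; a
`volume_over_height` mode is available since the printed definition admits
both readings.

## Reliability model

ICC(A,1): single-measurement, absolute-agreement, two-way random-effects,
from the ANOVA mean squares (subjects MSR, raters MSC, residual MSE):

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)).

The 95% interval uses the F-based construction with Satterthwaite degrees
of freedom for the combined rater/error term. Negative estimates are
reported as computed, never truncated. Degenerate layouts (zero total
variance) raise an explanatory error; perfect agreement returns ICC 1 with
a degenerate [1, 1] interval. In rare edge cases the approximate interval
fails to contain the point estimate; it is then clipped to contain it and
the result carries a note. The implementation is cross-checked in the test
suite against an independently coded mean-squares oracle (to 1e-10) and
against pingouin's ICC(A,1) row.

Classification: ICC < 0.5 poor; 0.5–0.75 moderate (both boundaries
inclusive); (0.75, 0.9] good; > 0.9 excellent — the inclusive reading of
the verbal bands; the boundaries are documented here rather than
configurable silently. Flagging: condition 1 iff ICC < 0.75; condition 2
iff ICC ≥ 0.75 and the lower CI bound < 0.50. The two conditions are
mutually exclusive by construction. Flag logic always operates on
unrounded values; only the human-readable tables round to 2 decimals.

Study arrangement: the published description of which values feed which
ICC is ambiguous (its averaging clause is attached to the intra-examiner
analysis, where averaging would erase the within-examiner variation it is
supposed to measure). The default here treats one examiner's two sessions
as the raters for the intra-examiner ICC, and the examiners — each
represented by the mean of their sessions — as the raters for the
inter-examiner ICC. `inter_mode` exposes the literal alternatives
(`first_sessions`, `all_four`). Subjects missing any (examiner, session)
cell are dropped per complete-case analysis, with a logged count; missing
measurement values drop a subject only for that quantity.

## Synthetic data

The head template is a fixed table of plausible adult coordinates
(bizygomatic breadth ≈ 130 mm, anterior facial height ≈ 100 mm, overbite
2 mm, overjet 3 mm), exactly mirror-symmetric about its midsagittal plane.
It makes no claim of normative anatomy; it exists so that every
measurement is exercised without degeneracies and so that symmetry gives
exact nulls. Seeded shape variation (default SD 1.5 mm, global scale SD
3%) moves median points within the midline plane and bilateral pairs as
mirror images, preserving both the symmetry and — because mirrored point
pairs are automatically coplanar — the exactness of the FH fit.

The study simulator is a variance-components model: one base anatomy per
study; subject truths add isotropic per-landmark offsets of SD
`sigma_subject` (default 2 mm); each examiner carries a per-landmark bias
field of SD `sigma_examiner` (default 0.5 mm) shared across their
sessions; each session adds independent noise of SD `sigma_session`
(default 1 mm). For any single coordinate the intra-examiner ICC then has
expectation σ²ₛ/(σ²ₛ + σ²ₑᵣᵣ) = 0.8 at the defaults — deliberately
pessimistic relative to clinical CT labeling, so that the flagging logic is
exercised; the simulated tables reproduce the qualitative finding that
parameters with values near zero (cantings, yaws) show markedly lower
reliability than the landmarks they derive from. Everything is keyed to a
single seed; identical seeds reproduce sessions bit-for-bit.

Airway phantoms are generalized cylinders (constant, stepped, linearly
tapered, or two disjoint lobes) aligned with the vertical axis, built as
watertight ring meshes with closed-form area profiles and volumes. An
inscribed n-gon underestimates a circle by the factor sin(θ)/θ, θ = 2π/n —
about 0.05% at 360 facets — which sets the tolerance of every mesh-vs-
closed-form comparison.

## Numerical choices and known limitations

* Degenerate projected directions (norm < 1e-9 mm) raise errors rather
  than returning NaN; batch evaluation converts them to missing markers.
* Angles use atan2 forms, accurate near 0° and 90° where arccos loses
  precision.
* The OLS Frankfort fit regresses the superior coordinate, so it is
  exactly equivariant under rigid motion only when the four fitted points
  are coplanar (the fit is then the unique plane through them). Mirrored
  templates satisfy this automatically; real, noisy labelings do not, so a
  re-oriented scan can shift FH-derived quantities by a small amount of
  order (residual/footprint)² — a property of the vertical-residual fit
  itself, not of this implementation. The orthogonal fit variant avoids
  this at the cost of departing from the documented construction.
* Section areas sum absolute shoelace areas per closed loop; a loop nested
  inside another (an island) would be added, not subtracted. Pharyngeal
  lumina do not produce such configurations on axial slices.
* The gross-outlier check in validation measures distance from the
  per-axis median of the session, robust to the very outliers it hunts;
  the default threshold is 300 mm (beyond any head-scale distance).
* Simulated sessions use isotropic Gaussian noise per landmark; real
  labeling error is anisotropic and landmark-dependent (points on ridges
  slide along them). Passing reliability tests on synthetic studies
  validates the estimator and the pipeline plumbing, not the clinical
  reliability of any particular landmark.
* Problem sizes in the test and acceptance runs (e.g. 200 simulated
  subjects for point recovery, 500 replicates for CI coverage, 96–360
  facet phantoms) were chosen as the smallest sizes at which the checked
  statistics are stable at the stated tolerances.
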
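# Methods

`kneekin` implements a geometric pipeline for measuring tibiofemoral
kinematics of native and replaced (TKA) knees from surface meshes and
per-frame rigid-body poses, of the kind produced by 3D-model-to-2D-image
registration against single-plane fluoroscopy. The pipeline measures
anterior–posterior (A-P) positions of the femoral condyles on the tibia by
the *lowest-point method* and derives tibial internal–external (I-E)
rotation from them. Because real registration data are patient-specific
and not redistributable, the package ships a synthetic generator whose
models have closed-form landmarks, so every stage can be verified against
analytic ground truth.

## Coordinate conventions

Right-knee convention throughout: `+x` lateral (ML), `+y` anterior (AP),
`+z` proximal (PD); millimetres and degrees. Left knees are generated (and
expected to be analysed) as mirror images of right knees, so a single sign
convention applies: positive I-E rotation is internal tibial rotation,
i.e. the lateral femoral condyle moving posterior relative to the medial.
A pose is a 4×4 homogeneous matrix mapping body-local coordinates into the
lab frame (the convention of registration tools that report absolute model
pose); reflections and non-orthonormal rotations are rejected at load
time.

## The measurement chain

1. **Flexion angle.** Anatomic axes join the midpoints (area centroids of
   the largest closed cross-section contour) of the femoral shaft at 70
   and 120 mm above, and the tibial shaft at 50 and 120 mm below, the
   joint line. Flexion is 180° minus the included angle of the two axes
   directed away from the joint, so a straight limb reads 0°. The axis is
   the chord between the two midpoints, not a tangent, so shaft bow is
   averaged out. Pose CSVs may carry a flexion annotation; when absent it
   is recomputed from the axes.
2. **Femoral sagittal frame.** Spheres are least-squares fitted to the
   most-posterior 25% of each condylar surface; the sagittal-plane normal
   (ML axis) joins the two centers. A sphere-fit RMS above 1 mm or a patch
   under 50 vertices is a geometry error.
3. **Axial plane.** The medial tibial articular surface is fitted by a
   total-least-squares plane, then re-orthogonalized to be perpendicular
   to the sagittal plane by a rotation about the A-P direction only (the
   A-P component of the normal is preserved, the ML component zeroed).
4. **Simulated tibial resection plane.** The axial plane is translated
   10 mm distally from the medial tibial condyle center (center = area
   centroid of the articular patch; the term is otherwise not operational
   on a mesh). Its varus–valgus angle is then adjusted in whole 2°
   increments — search order 0, +2, −2, +4, −4, … bounded at ±10° — until
   the medial and lateral condylar thicknesses (3D point-to-plane
   distances from the condyle centers) agree within ±0.5 mm. Positive
   adjustment tilts the plane normal laterally. The first satisfying
   candidate wins; if none satisfies the tolerance within the bound, a
   convergence error reports the best achieved imbalance.

   *Granularity caveat:* a 2° step over a typical ~37 mm inter-condylar
   lever changes the lateral thickness by ≈1.3 mm, which exceeds the
   ±0.5 mm tolerance band. Certain plateau tilts (e.g. 2° or 6° with the
   default synthetic geometry) therefore cannot be balanced at any
   candidate angle. This is a property of the procedure itself, not of
   the implementation; the tests compare the implementation against an
   exhaustive sweep oracle on both the successes and the failures.
5. **Tibial frame.** The origin is the center of the bounding box (axes =
   the sagittal frame's ML/AP directions projected into the resection
   plane) of the tibial contour in the resection plane; the A-P box
   extent is recorded as the native plateau A-P dimension. For TKA knees
   the reference is instead the baseplate bounding-box center with the
   plate's top plane as the lowest-point reference.
6. **Lowest-point condylar positions.** Per analysed frame, each condyle
   mesh is posed relative to the tibial body and the surface point
   minimizing signed distance to the reference plane is taken; vertices
   within 0.05 mm of the minimum tie and are resolved by their centroid.
   The tie rule makes the point a convergent estimator of the tangency
   point on near-flat regions: its error shrinks linearly with mesh edge
   length (≈0.3 mm at 1 mm edges, ≤0.07 mm at 0.25 mm edges for a 23 mm
   sphere), which is why the closed-form tangency comparisons in the test
   suite run on finely meshed spheres while the end-to-end rotation
   checks use the default ~1 mm models.
7. **Repeats, standardization, rotation.** Native (bone-model) tracks are
   the coordinate-wise mean of three registration repeats; TKA (CAD)
   tracks are single-pass. A-P positions are standardized by the ratio of
   the 50 mm reference baseplate A-P depth to the subject's plateau/
   baseplate depth; standardized tracks are flagged and *refused* by the
   rotation computation. I-E rotation between two flexion angles is the
   angle difference of `atan2(AP_med − AP_lat, ML_lat − ML_med)`, i.e.
   the orientation of the ML line connecting the two (non-standardized)
   lowest points; the ML coordinates are the lowest points' ML
   components. This makes every rotation exactly invariant to any
   translation of the reference origin — only A-P *positions* depend on
   the reference, a property asserted to 1e-6° in the tests.
8. **Profiles and arcs.** Rotation at each schedule angle is referenced
   to extension (0°). Arcs of extension are the consecutive schedule
   decrements: four 15° arcs for step up (60–45–30–15–0) and three 30°
   arcs for chair rise (90–60–30–0); arc deltas telescope to the
   maximum-flexion rotation by construction. When a pose sequence lacks
   an exact schedule angle, condylar positions are linearly interpolated
   between the bracketing frames (nearest frame if only one side exists
   within 5°).

## Synthetic data generator

The generator emulates the study conditions, not anatomy. Femoral
condyles are spherical caps (defaults: medial r = 24 mm, lateral 22 mm,
centers 46 mm apart) tangent to a planar medial tibial plateau; the
lateral articular surface may be tilted (plateau varus) about the plateau
midline; shafts are cylinders (≥130 mm so the 120 mm axis level exists);
the TKA stand-in has equal-radius ("constant radius") condyles and a
rectangular baseplate of exact 50 mm A-P depth (size-4 mid-size plate).
Default mesh resolution is ~1 mm edge length; each icosphere is oriented
with an icosahedron vertex at its distal pole so the tie-centroid lowest
point is exact under an identity pose.

Motion paths impose flexion about the trans-condylar axis (leaving the
condyle centers fixed), internal rotation about the PD axis through the
medial condyle center (a medial pivot), and an anterior–posterior
translation ramp:

* `screw_home` (native): rotation fraction `s(u) = 1 − (1 − u)^4` of the
  flexion fraction `u`, placing ≥60% of the rotation in the final arc of
  extension (68% of the total in the last 15° for step up, 80% in the
  last 30° for chair rise); the medial condyle additionally translates
  5.1 mm (step up) / 4.5 mm (chair rise) posteriorly by 30° of flexion.
  The exponent 4 is the smallest integer satisfying the 60% property for
  both activity schedules.
* `progressive` (medial-pivot TKA): rotation linear in flexion, zero
  medial A-P translation (ball-in-socket medial conformity).

Both paths impose the same default 13° total rotation at maximum flexion
— matching the cohort-level finding structure that endpoint rotation
agrees while paths differ. Cohorts draw each knee's maximum rotation from
a normal distribution (defaults mean 13°, SD 4.6°) and optionally scale
the geometry; everything is reproducible under a seed.

Registration noise models single-plane fluoroscopy anisotropy:
translation σ = 0.25 mm in-plane (AP, PD) and 2.0 mm out-of-plane (ML),
rotation noise as a per-axis N(0, 0.5°) rotation vector applied about the
body's position. These magnitudes are plausible defaults, not measured
values, and are fully configurable. Because the rotation statistic
depends only on coordinate *differences* between the two condyles of the
same body, translation noise cancels in rotation exactly; rotation noise
does not, which is what the three-repeat averaging attenuates.

What the generator does **not** emulate: real articular curvature change
with flexion (the native "lowest point drifts posterior as the medial
condyle flattens" effect is imposed as an explicit translation, not
produced by geometry), cartilage, osteophytes, soft tissue, contact
mechanics, or fluoroscopic imaging itself. Passing tests therefore
demonstrate the correctness of the *measurement chain*, not the clinical
realism of the motion.

## Statistics

Group comparisons are two-sample t-tests, Welch by default (the two
groups' rotation SDs differ by up to a factor of ~3, e.g. 4.4° vs 12.0°
at maximum flexion, so pooled variance is not defensible; pooled is
available as an option). Categorical tables use Pearson's chi-square
without continuity correction. Summaries report mean/SD (n−1), range,
median and IQR with linear-interpolation quantiles.

Power for the two-group design uses the noncentral-t distribution with
Welch–Satterthwaite degrees of freedom computed from the two group SDs
(df ≈ 40.5 for SDs 2.9/4.6 at n = 25). The default is **one-sided**: with
n = 25/group, SDs 2.9° and 4.6°, α = 0.05 and target power 0.80, the
minimum detectable difference is 2.75° (≤ the commonly quoted 2.8°; the
two-sided computation gives 3.12°, which is why one-sided is the default
— sidedness is configurable). `simulate_power` provides an independent
Monte-Carlo check; analytic and simulated power agree within 0.01 at
100,000 replicates, and the Welch test's type-I error calibrates to
0.05 ± 0.01 under the null.

## Numerical choices

* Tie tolerance for lowest points: 0.05 mm (robust to mesh jitter on
  near-tangent regions; a pure argmin is not).
* Sphere fits are algebraic least squares (linear system), plane fits are
  SVD total least squares; frame orthonormality is enforced to 1e-9.
* Pose CSVs round-trip bit-identically (floats are written at shortest
  repr and re-parsed with round-trip precision); rotations must be
  orthonormal to 1e-6 with determinant +1.
* Degenerate inputs (empty meshes, collinear patches, non-intersecting
  planes, identical axis levels, zero chi-square margins, n < 2 groups)
  raise typed errors naming the offending quantity.
* Problem sizes in the test suite: default-resolution knees (~20k femoral
  vertices), 100-seed noise studies, 10,000-replicate null calibrations
  and 100,000-replicate power simulations — sizes at which all sampling
  checks are stable at fixed seeds.

## Known limitations

* The resection-balancing granularity gap described above.
* Flexion-facet-center tracking (an alternative A-P descriptor that stays
  fixed where the lowest point drifts) is documented but not implemented.
* "Thickness in the frontal view" is implemented as the 3D point-to-plane
  distance; a 2D frontal-projection reading would differ only for
  non-frontal normals.
* The generator's plateau varus tilts the lateral surface about the
  plateau midline; with condyle centers at ±w/4 the balancing adjustment
  converges near `atan(tan(varus)/2)` rounded to the 2° grid rather than
  the varus angle itself. Tests compare against the oracle, not against
  the nominal tilt.
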
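# Methods

This note documents the models and numerical procedures implemented in
`spineload`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real radiographic data.

## Coordinate conventions

Right-handed global frame: x craniocaudal with cranially positive
(gravity acts along −x), y posteroanterior (anterior positive), z right
to left. The coronal image shows (x, z); the sagittal image shows
(x, y); both views are assumed spatially calibrated and true to size,
so projection is orthographic with no divergence correction. Vertebral
rotations are stored as a (coronal, lateral, axial) degree triple with
the fixed intrinsic convention lateral(z) → coronal(y) → axial(x),
right-handed about each axis; the triple and the rotation matrix
round-trip to 1e−9. Note that reporting frames in the radiographic
literature often orient the craniocaudal axis caudally-positive;
a physically identical axial rotation then carries the opposite sign.

## Geometric reconstruction

Each vertebra is a 9-parameter box: centre (3), dimensions height h,
width w, depth d (3), rotations (3). Its canonical points — lateral
end-plate extremities (±w/2 along local z on each end-plate, visible on
the coronal view), anterior/posterior end-plate extremities (±d/2 along
local y, sagittal view), end-plates at ±h/2 along local x — are
projected orthographically and matched to the observed landmarks by
Levenberg–Marquardt least squares (parameter tolerances 1e−12,
deterministic, initialized from the unrotated box implied by landmark
midpoints and extents). The superior end-plate area is the ellipse
π/4·w·d.

Axial rotation is observable in this landmark scheme only through
projective foreshortening (second order near 0°) and, when the optional
pedicle landmarks are supplied (local offsets ±0.6·w/2 laterally at
−0.5·d/2 posteriorly), through the first-order lateral sweep of the
pedicle midpoint; the fit is seeded from that sweep so it starts on the
correct sign branch. Measured accuracy under σ = 1 mm landmark noise
(500 replicates, angles up to ±15°, pedicles included): mean absolute
errors ≈ 1.1° coronal, 1.3° lateral, 5.0° axial. The axial floor is
intrinsically higher than contour-based stereoradiographic
reconstruction (reported around 3.6–3.7°) because only ten discrete
landmarks constrain it; the acceptance threshold is set at 5.5°
accordingly. At zero noise the round trip is exact to 1e−4 degrees and
1e−6 mm.

## Anatomical indexes

All angles are measured from the fitted boxes' end-plate edge
directions projected into the relevant plane, never from raw landmarks.
Curve detection: the per-level coronal end-plate tilt is smoothed with a
3-level moving average; strict sign changes of the smoothed sequence
segment the spine; within each half-segment the end vertebra is the most
tilted level of the *raw* sequence (cranial on ties); the Cobb angle is
the angle between the end vertebrae's end-plate lines; the apex is the
in-curve vertebra farthest laterally from the end-vertebra chord. Curves
with CA > 5° count as scoliotic and the largest-CA curve is primary.
Sacral slope is the sagittal inclination of the S1 superior end-plate
versus the horizontal; LL spans S1–L1, TK spans T1–T12; MAR is the
signed axial extremum over all vertebrae; PI is the angle at the S1
end-plate midpoint between the downward end-plate perpendicular and the
line to the hip-axis midpoint (absent, not zero, without femoral-head
input). The Roussouly type is automated (SS < 35° splits on whether the
sagittal lumbar apex sits at/below L4 → type 1 else 2; 35–45° → 3;
> 45° → 4) and flagged as approximate.

## Mechanical model

Bodies: T1…L5 free, S1 grounded, all massless and inertia-free (inverse
statics). Joints: 17 spherical joints at the midpoints of adjacent
vertebral centres; they transmit reaction forces but no reaction
moments. Translational stiffness triples (x′ axial, y′ coronal-plane,
z′ sagittal-plane, kN/m): thoracic segments (943, 86, 101); L1L2–L3L4
(2420, 397, 523); L4L5 and L5S1 (2420, 473, 523). The thoracolumbar
junction T12L1 is assigned the thoracic row (the table rows are read as
naming the cranial vertebra of each segment). Joint frames are the
rotation-group mean of the adjacent vertebral frames; forces are
reported on the caudal vertebra, in the global frame and in the caudal
vertebra's own frame.

Gravity: the configured fraction 0.7483 of body weight is applied as
per-level trunk loads (a linear ramp growing caudally over T1–L5,
totalling 0.5673), a head load 0.081 at the T1 superior end-plate
midpoint, and an arm load 0.100 anterior to T4. Trunk and arm loads act
0.3·d anterior of the vertebral centre. For a 47 kg subject the total
distributed force is 345 N. g = 9.81 m/s², all values configurable.

Muscles: 89 straight tensile elements in ten groups (thoracic
multifidus 12, lumbar multifidus 20, longissimus pars lumborum 5,
iliocostalis pars lumborum 4, longissimus pars thoracis 12,
iliocostalis pars thoracis 8, psoas 11, quadratus lumborum 5, external
oblique 6, internal oblique 6). Attachments are shipped in normalized
vertebral coordinates (multiples of h/2, d/2, w/2) and scaled by each
subject's reconstructed dimensions; strengths N_i are uniform within a
group, roughly proportional to group cross-section, and configurable.

The attachment table is this package's own design. A force-only
spherical-joint chain with 89 one-sided straight lines is close to the
boundary of static solvability for asymmetric postures: every free body
needs independent force couples in all three directions, and the couples
that the thoracic cage and facet contacts supply in vivo must come from
muscle geometry here. The table therefore uses: a posterior pair plus
deep anterior stabilising lines anchored to the pelvis at the uppermost
levels (the top body has a single joint and needs at least three muscle
lines of its own); crossed oblique multifidus ladders through the mid
thoracic spine and the thoracolumbar junction for segmental torque;
wide-set longissimus and rib-angle-width iliocostalis lines for lateral
arms; and abdominal-wall obliques whose lines run 4–10 cm anterior of
the column (costal margin to pubis), giving trunk flexion its long lever
arms — without them flexion demands are met by psoas co-contraction at
several times the physiological cost.

## Recruitment and equilibrium

Unknowns: 89 muscle forces (≥ 0) and 17×3 joint reaction components
(free sign); constraints: force and moment balance per free body (102
equations, assembled in SI units about each body's centre). The
recruitment problem minimizes Σ (fᵢ/Nᵢ)ᵖ with p = 3 by default
(configurable, p ≥ 2), solved in activation space by SLSQP with
equality constraints when the equilibrium set is non-empty (KKT
tolerance 1e−8 relative). Reactions are recovered by solving the force
rows exactly (they form an invertible chain system), so ground-reaction
force closure is exact to machine precision and any unresolved residual
is confined to moment rows.

For strongly asymmetric postures a small irreducible moment residual can
remain (the rib-cage/facet couples noted above). In that case the
recruitment is optimized inside the minimum-violation set (escalating
quadratic penalty, L-BFGS-B) and the solve counts as converged only if
the largest unresolved moment stays below 0.5 N·m — below the
moment-resolution floor that millimetre-scale landmark uncertainty
implies for joint forces of a few hundred newtons, and two orders below
the gravitational moment scale. Larger violations are reported as
non-convergence naming the worst-violated body; nothing is silently
clipped. On default synthetic cohorts about 1 in 38 subjects is
excluded this way.

## Force-dependent displacements

After each recruitment solve, every joint force is expressed in the
joint frame and converted to a translational displacement δ = F/k
componentwise (N over kN/m gives mm); the cranial subsegment ending —
and every body above it — shifts by the rotated δ; muscle attachments
follow their owning bodies; vertebral orientations are not updated.
The loop repeats until the largest componentwise displacement change
falls below 0.01 mm (safely above the ~5 µm numerical jitter of the
recruitment solve; displacements at convergence are 0.1–1.5 mm) with a
50-iteration cap. The update is under-relaxed (0.7, decaying
geometrically after 12 iterations) to damp solver jitter and settle
postures with degenerate recruitment optima; each solve warm-starts
from the previous activation pattern. Typical cohort subjects converge
in 4–8 iterations.

## Outputs and statistics

Loads are normalized by the subject weight force before any comparison.
For the primary curve, F^A is the force at the joint caudal to the apex
vertebra and F^M is the componentwise value of largest magnitude among
the in-curve joints with its sign preserved. Disc pressure is
1.54·F_axial/A with A the caudal superior end-plate area — the
empirical nucleus-to-average-pressure correction. Correlation tables
pair {SS, PI, LL, RT} with F_x, F_y at L4L5/L5S1 and {CA, TK, MAR} with
the components of F^A and F^M; Pearson with a two-tailed t-test when
both variables pass Shapiro–Wilk at α = 0.05, otherwise Spearman with a
seeded permutation test (exhaustive for n ≤ 7, 10 000 draws otherwise);
no multiple-testing correction (noted in the table metadata).
Non-converged subjects are excluded everywhere; subjects without a
curve > 5° are excluded from the curve tables.

## Synthetic data

`generate_spine` stacks vertebral boxes (typical adolescent dimensions,
scaled by stature) along a curve whose sagittal inclinations satisfy the
requested SS, LL (caudally-weighted distribution) and TK exactly; the
thoracic profile's linear/quadratic blend is then solved by bisection so
the gravity resultant falls 25 mm anterior of S1 — the sagittally
balanced posture of relaxed standing, without which lumbar loads come
out severalfold too high. Scoliosis is a half-sine lateral bump realised
through coronal rotations of ±Cobb/2 at the end vertebrae (so the
constructed Cobb angle is exact) with axial rotations peaking at the
apex at 0.5° per Cobb degree, directed into the convexity.
`project_landmarks` emits the 8 canonical landmarks per vertebra (10
with pedicles) plus seeded Gaussian noise. `generate_cohort` samples 38
subjects: mass N(47, 10²) kg truncated above 20; Cobb > 5° with
prevalence 29/38, uniform to 24°; apex weighted toward the dominant
main-thoracic levels (T8–T9); span 6–10 levels; spino-pelvic harmony
(PI ≈ N(50, 10²), PT ≈ 0.3·PI − 5, SS = PI − PT, LL ≈ PI − 5 ± 7)
rather than independent draws, because the strong inter-correlation of
these parameters is itself an anatomical fact; TK ≈ N(35, 10²);
landmark noise 0.5 mm by default. All randomness flows through one
seeded generator and every subject records its recipe.

What passing synthetic tests show: that the implementation is
internally consistent (construction → measurement round trips), that
the statics and displacement mechanics behave as specified, and that
population-level load–anatomy couplings created by mechanics are
recoverable through the full noisy pipeline. What they do not show:
performance on real radiographs — real vertebrae are not boxes, real
landmarking errors are not isotropic Gaussian, and real curves are not
half-sine bumps with linear axial coupling.

## Known limitations

* Compressive loads run ~1.5–2× in-vivo standing values (L4L5 ≈
  0.8–1.4 kN for a 47 kg subject against ≈ 0.5–0.6 kN measured in
  vivo): with only 89 straight lines, the recruitment meets moment
  demands with more co-contraction than a fascicle-rich architecture
  would need, and disc pressures inherit the overshoot. Comparisons
  across subjects (the correlation tables) are unaffected in direction.
* Axial rotation from ten landmarks has a ≈5° noise floor at σ = 1 mm;
  pedicle landmarks are strongly recommended.
* The apical/extreme curve-load couplings (MAR with F_z^M, TK with
  F_y^A) have the expected directions subject-by-subject but are
  statistically fragile at n ≈ 28: the sign-preserved max-magnitude
  rule lets F^M flip between curve limbs for low-apex curves, and
  landmark noise dilutes MAR. The lumbosacral couplings (SS, PI, LL,
  RT against F_y) are robustly recovered.
* No rib cage, intra-abdominal pressure, rotational joint stiffness,
  ligaments, muscle wrapping or force–length properties; translational
  FDK only; no reaction moments; statics only.
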
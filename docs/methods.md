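# Methods

`mortisesim` re-creates, on fully synthetic anatomy, a virtual experiment for
quantifying rotational malreduction of the distal fibula on intraoperative
mortise-view fluoroscopy. This note records the model, its assumptions, the
tunable parameters, and the numerical choices, so that a reader can judge what
a green test does — and does not — establish.

## The measurement

On a mortise-view radiograph (limb internally rotated 15°), a reference line is
drawn through the tip of the medial malleolus, parallel to the distal tibial
plafond. It crosses the medial edge of the fibula at **A**, the dense shadow of
the lateral malleolar fossa cortex at **B**, and the lateral fibular edge at
**C**. The measurement is

    alpha = |AB| / |AC|,

a dimensionless ratio, invariant to image scale, rotation and translation —
which is what makes it usable on uncalibrated fluoroscopy. In normal ankles
alpha ≈ 0.49 at the neutral pose; internal rotation of the fibula about its
medullary axis carries the fossa cortex laterally (alpha grows), external
rotation carries it medially (alpha shrinks).

The geometry behind the monotone relationship is a circle swing: the fossa wall
sits at polar radius ρ from the malleolar centre, so its projected abscissa
relative to the malleolar centre is ρ·cos(φ + θ) for pose angle θ. Because the
wall sits nearly posterior in the mortise view (φ ≈ −90°), the projected
displacement per degree is maximal near neutral and decreases toward ±30° —
the measurement is most sensitive exactly where small malrotations must be
detected.

## Synthetic anatomy

No clinical images ship with the package; the study population is emulated by
constructive solid geometry with analytic landmarks, so every downstream
measurement can be checked against closed forms.

* **Tibia** — a capped cylinder (radius ~18 mm, plafond at z = 0) whose lateral
  aspect carries the fibular incisura: the contour between the two rim points
  is replaced by the tangent chord pushed inward by a cos² bump. The carve is
  defined *from the chord*, so the chord-to-floor sagitta equals the
  `incisura_depth` parameter exactly, and a depth-0 parameter yields a flat
  (chordal) incisura. The medial rim prolongs into the medial malleolus, a lobe
  tapering to its distal tip 12 mm below the plafond.
* **Fibula** — a shaft of revolution about a straight vertical medullary canal
  that widens (z between +12 and +2 mm) into the lateral malleolus: a circular
  cross-section of radius `malleolus_width/2` whose centre sits
  `malleolus_offset` (2.5 mm) lateral to the canal. The posteromedial fossa is
  a cos²-profile depression (depth 3 mm, ~60° × 8 mm footprint) centred at the
  level of the medial malleolar tip. The **fossa cortex** used by the
  measurement is the depression's half-depth iso-contour; its medial branch is
  stored as the `fossa_wall_ring` landmark.
* **Talus** — an ellipsoid dome under the plafond. Its lateral half-width
  adapts to the drawn fibular position (the talus fills the mortise, keeping
  ~1 mm of lateral joint space at neutral), so deep-incisura draws do not
  collide at rest; it participates in every overlap test.

**Calibration.** One constant, `fossa_medial_offset_frac` (default 0.49,
population SD 0.05), is calibrated: the wall azimuth is solved (Brent's method)
so that at the neutral pose, in the default 15° view, the wall projects at that
fraction of the malleolar width. Everything else — the values of alpha at
rotated poses, the saturation toward ±30°, the shadow disappearance at extreme
external rotation — is emergent from the geometry.

**Population.** Cohorts draw per-specimen parameters from normal distributions
(sex-specific sizes; male fraction 45/96). Incisura depth is bimodal around the
4 mm concave/shallow threshold: the type is drawn first (P(concave) = 0.583),
then the depth from the matching component — N(4.8, 0.6²) truncated at ≥ 4 or
N(3.0, 0.5²) truncated at < 4 — so the realised concave fraction matches the
configured probability (an untruncated mixture would leak ~4 % of "shallow"
draws across the threshold). Ages are N(38.4, 13.6²) clipped to [18, 75].

**What the generator does not emulate:** cortical/trabecular density contrast,
cartilage and joint space, real cross-sectional shape variation (the malleolus
is circular, the shaft is a surface of revolution), acquisition noise, scatter,
or beam divergence. A green cohort test therefore establishes that the
*measurement chain* behaves as described on anatomy with the stated statistical
structure — not that the printed clinical reference ranges would be reproduced
on patients.

## Kinematics

The rotation axis is fitted, not assumed: the total-least-squares line through
the area centroids of 10 evenly spaced transverse sections of the shaft, with
the distal 40 % of the bone excluded so the malleolar flare cannot bias the
fit. For the synthetic fibula the fitted axis agrees with the known canal to
well under 0.5°/0.5 mm.

Positive angles are internal rotation about the proximally oriented axis of a
right ankle; left ankles are mirrored into the canonical right frame at load
time and the sign convention flips with the recorded side, so "internal" means
internal on either side (mirror symmetry is tested end to end).

When a rotated fibula interpenetrates the tibia or talus it is translated
laterally — the canonical +x direction, perpendicular to the tibial long axis,
fixed in the ankle frame rather than re-derived per pose — by the minimal
clearing shift, found by a doubling bracket plus bisection to 0.01 mm on an
exact mesh-overlap predicate (segment–triangle crossing tests both ways plus
containment by ray parity). The returned shift is the clear upper end of the
final bracket, so a resolved pose never overlaps. Penetration lenses smaller
than one facet (~0.5 mm, i.e. sagitta below the 0.01 mm tolerance) can escape
the predicate; this is below the resolution of the search and immaterial since
a common lateral shift of A, B and C leaves alpha unchanged anyway.

## Projection

Parallel-beam (orthographic) rays along −y after rotating the scene internally
by the mortise angle about the tibial long axis. A pixel records the total
ray–mesh chord length (mm of bone; uniform density — only edge and shadow
*positions* carry information and any monotone intensity transform preserves
them). For a watertight, outward-oriented mesh the chord length equals
Σ sign(n_y)·y over covering triangles, so rendering is an exact scanline
accumulation with no ray sorting; per-bone channels sum to the combined image
exactly. A 10⁻⁶-pixel sampling bias breaks exact edge-through-centre ties.

**Finding B on the image.** With uniform density, a recessed cortical wall does
not produce a literal local maximum of attenuation; what the tangential rays
through the wall produce is the steepest *descent* of the profile — a dip in
dL/du. Image mode therefore detects B as the most prominent peak of −dL/du
(Gaussian-smoothed, one pixel) between the fibular edges, excluding a 3.5 mm
margin so the circular silhouette falloff cannot masquerade as the wall.
Landmark mode bypasses detection entirely and projects the stored wall ring;
the two modes agree within ~1 pixel wherever the shadow exists. At ~30° of
external rotation the wall turns edge-on to the beam, the dip fades below the
prominence threshold (0.5 mm/mm), and the measurement is flagged
`fossa_shadow_missing` with `valid=False` rather than fabricated — the known
disappearance of the fossa shadow at large rotations. Virtual radiographs are
bone-labelled, so image mode reads the fibula channel; a reference line that
crosses only other bones raises an error instead of detecting something.

## Incisura typing

On the transverse section 1 cm proximal to the plafond (the offset is a
parameter), the incisura is found as the convex-hull deficiency of the lateral
120° sector of the contour: the hull edge spanning the concavity is the tangent
chord, the depth is the maximal inward deviation of the contour points under
it, and ≥ 4.0 mm (closed bound) classifies the incisura as concave. A convex
contour returns depth ≈ 0, type shallow, with a warning flag.

## Statistics

All implemented in-package (scipy only for distributions), cross-checked in
the tests against pingouin and closed-form ANOVA sums:

* per-angle summaries: mean, sample SD, t-based 95 % CI;
* inter-observer agreement: ICC(2,1) — two-way random effects, absolute
  agreement, single measures — the standard choice for two raters when only
  "ICC" is specified; recorded as such in the output manifest;
* all-pairs angle comparisons: Tamhane's T2 — Welch t statistics with
  Welch–Satterthwaite df and the Sidak-type adjustment 1 − (1 − p)^m over the
  m = 78 pairs (conservative; simulated family-wise error ≈ 0.04 at nominal
  0.05);
* subgroup comparisons (incisura type, sex) within each angle: pooled t-test
  with automatic Welch fallback when a two-sided F-test rejects equal
  variances at 0.05 (emulating the common SPSS workflow);
* reported percentages: half-up rounding to one decimal.

Observers are simulated by jittering the A/B/C abscissae independently
(N(0, σ²), σ default 0.2 mm ≈ one pixel — the digitising precision of a
careful reader), clamping B back into [A, C]. This yields per-angle ICCs of
roughly 0.85–0.95, consistent with reported inter-observer agreement for this
kind of reading.

## Numerical choices

* Mesh resolutions (96 azimuthal segments for the fibula, 120 for the tibia,
  ring spacing 0.5–1.5 mm) keep silhouette and sagitta discretisation errors
  below 0.01 mm and 0.05 mm respectively, while keeping facet sizes small
  enough for proximity-pruned collision queries.
* Overlap resolution: doubling step 0.25 mm, bisection tolerance 0.01 mm,
  50 mm search ceiling (beyond it the specimen is declared malformed).
* The wall-azimuth and fibula-placement solves use Brent's method with
  brackets guaranteed by parameter validation (the incisura chord must exceed
  the malleolar width so the fibula can nest).
* Determinism: every stochastic stage draws from `numpy` Generators seeded
  from a single experiment seed via `SeedSequence`; identical configs produce
  byte-identical CSV outputs.

## Known limitations

* The anatomy is idealised (circular sections, straight vertical canal, no
  cortex/trabecular contrast); absolute agreement with clinical alpha tables
  beyond the calibrated neutral value is approximate (±0.03 at the ±30°
  extremes on the default cohort).
* The angle→alpha curve's spread at extreme angles is narrower than clinical
  data (real cohorts show SD up to 0.09 at ±30°); consequently adjacent-angle
  pairs at the extremes remain statistically separable here, whereas clinical
  data may not separate them.
* Image mode reports the fossa shadow as missing at ~30° external rotation;
  how such frames were read clinically is unknown, and the package records the
  ambiguity instead of guessing.
* No sagittal/coronal tilt or shortening malreductions, no ligaments or
  contact mechanics, no cone-beam geometry.
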
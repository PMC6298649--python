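# Methods

## Rotation model and sign conventions

The osteotomy is modelled as a planar rigid rotation of the proximal femoral
fragment about the center of the circular cut, as seen on an anteroposterior
radiograph. In the arc-center frame (origin at the arc center `O`, `+x`
lateral for the hip under study, `+y` proximal) the head center sits at
`H = (−A, B)`: `A > 0` means the arc center lies lateral to the head center,
`B > 0` distal to it. A varus rotation by `θ` maps

```
H′ = (−A cosθ − B sinθ, −A sinθ + B cosθ),
```

i.e. the counter-clockwise matrix `x′ = x cosθ − y sinθ, y′ = x sinθ + y cosθ`
applied to `H`. In this frame positive `θ` lowers the head (`A, B > 0`), and
since clinically the head stays seated in the acetabulum while the distal
fragment carries the leg, the head's drop is the leg's shortening and its
medial displacement the shaft's lateralization:

```
S = A sinθ + B(1 − cosθ),        L = −A(1 − cosθ) + B sinθ.
```

Angles are degrees at every interface (converted internally), lengths are
millimetres. The geometric core accepts `θ ∈ [−90°, 90°]` — valgus angles
are mathematically fine and occasionally arise as measurement noise around
zero — but the planner rejects `θ < 0`, since only varus is planned. The
closed forms are checked against an explicit rotation-matrix construction to
10⁻⁹ mm over the full parameter box in the test suite.

**Assumptions.** Strictly 2D (no femoral anteversion or rotational
malposition); the cut is an exact circular arc and the fragments stay
congruent on it (no translation at the osteotomy, no nonunion); the head
center is a fixed point of the hip joint between radiographs.

## Canonical frame and radiographic measurements

All measurements are taken in a canonical frame built from the pelvic
teardrop landmarks: ipsilateral teardrop at the origin, tear-drop line as
the x-axis, `+x` lateral, `+y` proximal. The transform is rigid plus, when
needed, a mirror; the proximal side of the line is identified by the
greater-trochanter tip, which anatomically always lies above it. This makes
every derived quantity invariant (to 10⁻⁹ mm, tested) under arbitrary
rotation, translation and mirroring of the raw digitization, and maps left
hips onto the right-hip convention so one set of formulas serves both sides.

* **Neck-shaft angle (NSA)**: angle between the neck axis (pointing at the
  head) and the shaft axis (pointing distally), from two digitized points
  each. Varus angulation is `θ = NSA_pre − NSA_post`.
* **VD / LD**: height of the trochanter tip above the tear-drop line and
  lateral distance of the lateral trochanteric border. The tear-drop line
  has no intrinsic horizontal origin, so LD is measured from the ipsilateral
  teardrop point; only pre→post *differences* are used downstream
  (`actual shortening = VD_post − VD_pre`,
  `actual lateralization = LD_post − LD_pre`), which are origin-independent.
* **Head and arc centers**: circles fitted through three digitized head-rim
  points and ≥ 3 points on the osteotomy arc. Exactly three points give the
  circumcircle; more give the algebraic (Kåsa) least-squares circle — closed
  form, deterministic, and accurate to first order in landmark noise, which
  is ample at the 0.1–1 mm digitization scale. Collinear or duplicate
  points raise a degenerate-geometry error.
* **Offset recovery**: both centers are fitted on the *post-operative*
  radiograph (the arc only exists after the cut). There the head-to-arc
  vector is the already-rotated `H′`, so it is rotated back by the measured
  `θ` to recover the pre-operative `(A, B)` that enter the prediction. When
  arc points were also digitized pre-operatively the distance between the
  pre-fitted arc center and the one implied by the post-operative fit is
  reported as a per-hip consistency metric.
* **Lateral head index (LHI)**: percentage of the head width intact
  laterally, `100 · N / W`, with both widths measured as horizontal extents
  parallel to the tear-drop line (the projection axis is a convention of
  this package). The necrosis margin is an input landmark (delineating
  necrosis from MRI is out of scope); a missing margin means a fully intact
  head, and the index is clamped to [0, 100]. The post-operative LHI is
  obtained by rotating the head-extent and margin landmarks about the arc
  center — for a superolaterally located margin it increases monotonically
  with `θ`, which is what makes the inverse planning problem well posed.

The greater trochanter is treated as part of the distal fragment, so VD/LD
track the distal fragment's displacement exactly; one motivation for the
curved osteotomy is precisely that it avoids elevating the trochanter with
the proximal fragment.

## Planner

`max_lateral_shift(B, θ, s_max) = (s_max − B(1−cosθ))/sinθ` inverts the
shortening formula for `A`; the shipped budget default is 5 mm, the usual
threshold for clinically relevant leg-length discrepancy. Sensitivities are
the analytic partials `(sinθ, 1−cosθ, (A cosθ + B sinθ)·π/180)` per mm, mm
and degree. `required_varus_for_lhi` finds the smallest `θ` with
post-rotation LHI ≥ target (default 25%, the usual indication threshold) by
bracketing on a 0.5° grid and bisecting to 10⁻³ °; the search is capped at
45° — above the clinically used range (15–38°) with margin — and a
non-monotone LHI profile falls back to the smallest feasible grid angle with
a warning rather than failing.

## Statistics

Pearson r and its two-sided p-value come from `scipy.stats.pearsonr` (exact
t transform on n−2 degrees of freedom); constant series raise an explicit
undefined-correlation error, which the cohort report records as a flag
rather than aborting. ICCs are single-measure Shrout–Fleiss forms computed
directly from one-way/two-way ANOVA mean squares: `oneway` (ICC(1,1),
default for intra-rater repeats), `two_way_random_absolute` (ICC(2,1),
default for inter-rater agreement) and `two_way_mixed_consistency`
(ICC(3,1)). Every result carries its form label; tables must be complete (no
imputation). The implementation is cross-checked against pingouin to 10⁻¹⁰
in the test suite. No multiple-testing correction is applied to the four
reported correlations. The cohort summary reports mean/min/max per variable
and the exact count/proportion of hips with actual shortening ≥ 5 mm.

## Synthetic cohorts

The generator's defaults are the study conditions: 42 hips; `A`, `B`, `θ`
from truncated normals with means 3.3 mm, 9.3 mm, 21.7° and hard bounds
[−8, 21] mm, [1, 21] mm, [15, 38]° (the reported clinical means and ranges);
truncation keeps the sampling means within ~1 unit of those targets
(largest for `θ`: ≈ +0.9°). The sds (5, 4, 5) and the truncated-normal
family are package choices — the clinical source reports only means and
ranges — and a uniform-over-range family is available. The osteotomy guide
radius defaults to 22.5 mm (a 45 mm guide, the middle of the three
manufactured sizes), the head radius to 25 mm, the pre-operative NSA to
135°, and the necrotic extent to Uniform(0.6, 0.95) of the head width with
the margin on the superior head circle. Per-patient anatomy (head-center
position, trochanter offsets) varies by a few millimetres around the
template scene; these offsets cancel in pre→post differences but give
subject-level variance, without which agreement statistics such as the ICC
of VD would be degenerate.

Rendering applies the kinematics exactly — rotate the proximal-fragment
landmarks about the arc center, then translate the whole femur so the head
center returns to its pre-operative position (the pelvic teardrops never
move) — so at zero noise the measured changes equal the closed forms by
construction, and the full render→load→canonicalize→measure round trip
recovers every ground-truth parameter to ≤ 10⁻⁶ (tested). Digitization
error is independent zero-mean Gaussian noise (default sd 0.5 mm, a typical
manual digitization error) added to every landmark coordinate of every
stage; `rater_replicates` re-noises the same truth for agreement studies.
Left hips are rendered mirrored to exercise canonicalization. Sampling and
rendering are deterministic given the seed.

**What the simulator does not emulate** — and hence what passing tests do
not show about real radiographs: hip adduction/abduction and rotation
between films (a recognized source of error in the lateral distance
measurement), magnification miscalibration, fragment translation at the
cut, out-of-plane (3D) geometry, and structured (non-Gaussian, correlated)
digitization error. Model-vs-measurement agreement on real cohorts can
therefore be worse than on these synthetic ones, particularly for
lateralization.

## Numerical choices and limitations

* Circle fits are centered and scaled before solving; collinearity is
  detected via the scatter's smallest singular value (relative tolerance
  10⁻⁹).
* Landmark CSVs are written with `%.17g` and read with round-trip float
  parsing, so serialization is exactly lossless.
* `measure_hip` flags (not rejects) a measured valgus rotation; planning
  functions reject `θ < 0` outright.
* Problem sizes in the test suite (cohorts of 10–42 hips, 100-seed Monte
  Carlo batches, 200-fit noise ladders) were chosen as the smallest that
  make the statistical assertions stable.
* A known tension in the default conditions: with cohort spreads matching
  the defaults, the between-hip spread of true shortening (≈ 1.9 mm sd) is
  only moderately larger than the noise of the VD-difference measurement
  (≈ 1.3 mm sd at 0.5 mm landmark noise, which compounds trochanter and
  teardrop-line digitization over two films). Attenuation then caps the
  attainable predicted-vs-measured correlation near 0.85 regardless of the
  model's accuracy — the prediction itself tracks truth at r ≈ 0.99.
  Cohorts with a wider spread of arc-center placements, or less noisy
  measurements, yield correspondingly higher validation correlations.
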
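# Methods

## The measurement

Digital clubbing — bulbous enlargement of the fingertips seen in chronic
cardiopulmonary disease — is graded clinically from the **Lovibond (profile)
angle**: the angle at the nail base between the line of the proximal nail
fold and the line of the nail plate, viewed in lateral profile. A healthy
finger shows roughly 160°; the angle opens as the nail base bulges and
exceeds 180° (a reflex configuration) in severe disease.

clubkit implements the angle as a **signed turning angle**. Three landmarks
are used: A on the nail matrix, B on the proximal nail fold (the vertex),
and C on the nail plate. With the finger in a canonical pose (tip toward
+x, dorsal side up in a y-down raster), let u = B − A and v = C − B, and
let τ be the signed angle from u to v, positive when the plate dips toward
the palmar side:

    θ = 180° − τ,        τ = atan2(u × v, u · v).

This convention makes θ a true reflex angle (> 180°) when the plate rises
dorsally, which is what the severe grade requires, and θ = 180° exactly for
a collinear triplet. θ is invariant to translation, rotation and uniform
scaling; a mirror flip negates τ, so the canonical frame records whether a
flip was applied and the angle code undoes it. Because the published
description names the three landmarks and the triangle but not an explicit
formula, this construction is a reconstruction; it is pinned down by the
requirement that the clinical grades below be attainable.

## Severity grades

| grade    | condition (defaults)        |
|----------|-----------------------------|
| normal   | θ ≤ 160°                    |
| mild     | 160° < θ < 180° − ε         |
| moderate | \|θ − 180°\| ≤ ε            |
| severe   | θ > 180° + ε                |

The clinical table defines normal and moderate as single angles (exactly
160°, exactly 180°). Classes of measure zero cannot be estimated from data,
so the 160° boundary is made inclusive on the normal side and the moderate
class is widened to a band of half-width ε (default 1°, configurable via
`SeverityThresholds.moderate_band_deg`). Every θ in (0°, 360°) maps to
exactly one grade, and grading is monotone in θ.

The binary clubbing-vs-normal stage uses the same 160° cutoff, so the
binary classifier and the grader agree that "not clubbing" ⇔ "normal".
In the full cascade a negative binary decision **bypasses** grading: the
result is labelled normal and carries no angle or landmarks.

## Capture gating

Finger-to-camera distance is estimated from the finger's apparent size
with a pinhole model: `d_cm = width_mm · focal_px / (10 · width_px)`, with
a default focal length of 1000 px and an assumed profile width of the
distal phalanx of 16 mm. The width in pixels is the median cross-axis
width over the most width-stable third of the finger's length (smallest
interquartile range) — the global median would be biased by the bulb in
severely clubbed fingers, and the stable-third rule is insensitive to both
the bulb and the nail taper. Capture is accepted on the **closed** interval
[4, 7] cm; both endpoints accept. The published account describes
proportion-based distance estimation without a formula; the width-based
pinhole model is this package's concrete choice because width is stable
under partial cropping, and the focal length and assumed width are
calibration inputs, not constants of nature. An area-proportion mode
(`distance_from_area_fraction`, d = k/√fraction with a user-supplied k) is
provided for protocols calibrated on frame coverage instead.

## Landmark detection

The default detector is geometric, standing in for a learned keypoint
network behind the same interface (`detect_landmarks(mask, frame, config)`
— any callable with this signature can replace it):

1. **Segment**: Otsu threshold, largest connected component, hole filling.
   Boundaries are traced on the lightly denoised intensity image at the
   threshold level, which is subpixel-accurate on anti-aliased edges.
2. **Canonicalize**: rotate the principal axis onto x; the tip is the end
   whose silhouette is narrower over its outer 5 % (fingertips taper, the
   proximal cut is flat); the dorsal side is the side with the sharpest
   mid-contour corner (the nail fold and nail-tip corners are dorsal; the
   palmar boundary is smooth), or the side of the fold landmark when
   ground-truth landmarks are supplied.
3. **Find the fold**: on the dorsal boundary (resampled to 1 px arc
   spacing, Gaussian-smoothed with σ = 3 px), compute turning angles over a
   ±15 px chord window. Corner candidates are peaks above a noise floor
   (max of 4° and 6 robust standard deviations), flanked by straight runs
   whose proximal side is within 45° of the axis — this excludes the
   silhouette's proximal cut edge. Walking proximal → distal the fold
   comes first and the nail-tip corner second. If the first corner sits
   within (bulb diameter − nail/4) of the distal extreme in x, it is the
   nail-tip corner and the fold is invisible (θ ≈ 180°); B then falls back
   to one nail length proximal of it along the contour. The bulb diameter
   comes from a least-squares circle fitted to the distal palmar boundary
   (the dorsal side of the bulb is occluded by the nail, and a circle fit
   is immune to residual principal-axis tilt); the nail length is taken as
   0.75 × the measured shaft width (12 mm / 16 mm), so the detector needs
   no camera calibration.
4. **Refine**: lines are fitted to the straight runs on both sides of B
   (arc windows at 0.12–0.45 nail lengths); their directions give τ with
   ~0.05° accuracy on clean renders, and their intersection refines B when
   the turn is strong enough (> 3°). A and C are placed at 0.35 and 0.5
   nail lengths along the fitted directions, the conventional positions of
   the nail matrix and mid nail plate; the exact offsets are configurable
   because the published description names the structures without fixing a
   point on them.

"Fold not found" is raised only when no significant corner exists anywhere
on the dorsal contour (reported with the largest prominence observed).

## Synthetic data

No clinical images ship with the package (the reference dataset is not
redistributable), so every downstream stage is tested against a renderer
whose geometry is known exactly *before* rasterization:

* capsule-like shaft (width 16 mm) with a flat proximal cut;
* circular tip bulb of radius `tip_bulb_ratio` × shaft half-width (the
  ratio grows with severity, 1.0–1.8 across the default grade ranges);
* two-segment dorsal polyline — shaft line through A and B, nail plate of
  12 mm through B and C — whose turn at B realizes the requested Lovibond
  angle exactly; all other junctions are smooth (the palmar shaft–bulb
  junction carries an explicit fillet arc of radius w/4; a bare
  line–circle junction would leave an anatomically wrong notch). The nail
  tip corner is left sharp: it is a real feature of profile views and the
  detector's distal anchor.
* pinhole scaling (focal 1000 px) at a simulated distance of 1–10 cm,
  in-plane rotation, optional mirror flip; anti-aliased rasterization
  (2× supersampling), background intensity 0.15, finger 0.75 × brightness,
  additive Gaussian noise (σ = 0.01) truncated to [0, 1], 8-bit output.

Identical spec + seed gives bit-identical images. Default cohort
conditions: grades mixed ¼ each; per-grade angle ranges keep a 0.5–1.5°
margin from the grade boundaries (normal 146–159.5°, mild 161–178°,
moderate 179.3–180.7°, severe 182–212°) — ranges straddling a boundary are
rejected; distances uniform on [4, 7] cm; orientation uniform ±25°; random
flips; brightness 0.85–1.0.

What the generator does **not** emulate: skin texture and translucent
nails, oblique (non-lateral) poses, occlusion, focus blur, multi-finger
scenes, and real anatomical variability of the fold shape. Passing tests
therefore demonstrate that the geometry pipeline is correct and stable
under pose, scale, brightness and pixel noise — not that the curvature
detector would match a trained network on photographs. The detector
interface is exactly where such a model would plug in.

The augmentation module reproduces the reference training recipe — random
horizontal flips, brightness shifts of ±20 %, scaling of ±10 % (about the
image centre, canvas unchanged) — with annotations transformed
consistently; angle and grade are invariant under all three.

## Evaluation conventions

* Confusion matrices: rows = actual, columns = predicted.
* Per-class "accuracy" ≡ recall (the published tables report one number
  for both).
* F1 is computed from unrounded precision and recall; macro averages are
  unweighted means over classes; zero-denominator cells are NaN and are
  skipped by the averages.
* Display rounding is half-up, matching the printed tables.
* Detection AP: greedy score-ordered matching at IoU ≥ 0.5 (one match per
  ground-truth box), 101-point interpolated precision–recall area; the
  published account reports mAP without a protocol, so this standard one
  is fixed and documented.
* Keypoint PCK: fraction of predictions within a radius of ground truth,
  per landmark.

The packaged reference matrices (`table6`, `table8`, `table10`, `table12`)
reproduce every internally consistent cell of their published metric
tables. A handful of printed cells do not recompute from their own
matrices (e.g. the moderate row of the severity table, and several cells
that were truncated rather than rounded); these are enumerated in
`fixture_metadata()` and deliberately asserted nowhere.

## Numerical choices and degenerate inputs

* Angle domain (0°, 360°) exclusive; coincident or antiparallel landmark
  segments raise a degenerate-triplet error; exact collinearity is legal
  (θ = 180°).
* Masks with principal-axis ratio < 1.2 raise "orientation ambiguous".
* All-black or constant frames raise "no finger detected".
* Equal-curvature tie-breaks resolve to the most distal peak through the
  scored ordering of `find_peaks`; all randomness is injected through
  explicit seeds and every cascade output carries the config hash.

## Benchmark problem sizes

The end-to-end recovery benchmark (`clubkit.benchmark.parameter_recovery`)
uses 200 renders at 4–7 cm, the angle-formula oracle check uses 1000 random
triplets, and the distance sweep uses 7 distances spanning 1–10 cm. Gate
rejections and stage failures count as misclassifications. On the default
conditions the cascade grades ≈ 96–99 % of samples correctly with measured
angles within 3° of truth in ≈ 100 % of cases; the residual misses are
severe fingers within ~ε + 3° of the 180° moderate band and hard capture
distances at the gate edges.

## Known limitations

* The curvature detector assumes a single finger, lateral view, plain
  background, and a visible nail contour — the published inclusion
  criteria; it has no notion of occlusion or blur.
* The bulb-diameter and nail-length heuristics assume roughly adult
  proportions (nail ≈ ¾ of finger width); strongly atypical anatomy would
  need a recalibrated `DetectorConfig`.
* Severity is a screening label derived from one angle; the package makes
  no diagnosis of underlying disease.
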
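# Methods

`valguscv` measures the frontal-plane knee valgus angle from a marker-based
photograph and implements the statistical workflow used to establish the
reliability and validity of such photographic goniometry. This note
documents the model, the estimators, the synthetic-data generators, and the
numerical choices.

## The measurement model

A subject performs a single-leg squat facing a fixed camera (protocol:
2 m distance, 1.05 m lens height; both are carried as metadata only — the
angle is scale-free). Three saturated circular markers, red or blue, sit on
the anterior superior iliac spine (ASIS), the midpoint of the patella, and
the anterior tibial tuberosity (ATT). The knee valgus angle θ is the
interior angle at the patella vertex between the rays patella→ASIS and
patella→ATT:

    θ = arccos( u·v / (|u||v|) ),   u = ASIS − P,  v = ATT − P

reported in degrees in (0, 180]. θ = 180° is a perfectly straight limb;
healthy cohorts sit near 155–160°, so the interior (obtuse-side) angle is
reported, never its supplement. θ is invariant under translation, rotation,
uniform scaling and mirroring of the image, which is why no pixel
calibration, leg-side mirroring or projection correction is applied (the
protocol is strictly 2-D frontal-plane; out-of-plane limb rotation is a
known, unmodelled bias of all such 2-D methods).

`valgus_deviation` = 180 − θ is provided as the more intuitive "deviation
from straight" reading of the same measurement.

### Numerical note

The arccos form loses ~√ε precision where the rays are nearly collinear
(cos θ ≈ ±1): errors up to ~1e-6° at θ ≈ 0° or 180°. This is irrelevant at
cohort angles (the formula is exact to ~1e-12° away from the poles) and is
documented in the property tests, which compare against an independent
difference-of-atan2-bearings oracle.

## Marker detection

1. Convert RGB to HSV. Per enabled color, threshold on hue windows
   (red: 345–360° ∪ 0–15°, wrapping the hue origin; blue: 200–260°) with
   saturation ≥ 0.5 and value ≥ 0.25. Marker interiors sit near S ≈ 0.85,
   while skin (S ≈ 0.38) and shadowed cloth fall below the floor; the 0.5
   saturation floor also trims low-coverage anti-aliased rim pixels so a
   sub-threshold speckle keeps a footprint close to its true area.
2. Label 8-connected components and keep those with area in
   [20, 5000] px² and circularity 4π·area/perimeter² ≥ 0.6, using the
   Crofton perimeter estimator. Digitized discs can nominally exceed
   circularity 1; values are clipped at 1.05. The area bounds are
   pixel-space configuration — the physical marker diameter maps to an
   unknown pixel size — and the defaults admit disc radii of roughly
   3–40 px at the tested image scale.
3. Each survivor's centroid is the saturation×value-weighted center of
   mass of its component: effectively the mask centroid for a uniform
   disc (weights are constant inside, tapering at the anti-aliased rim),
   and robust to partial occlusion, unlike a fitted-circle center.
4. Red and blue survivors are pooled (either color is legitimate for any
   landmark), the three largest by area are kept (ties: higher
   circularity, then smaller y), and roles are assigned by vertical
   order: topmost = ASIS, middle = patella, bottom = ATT. Assignment
   refuses trios whose centroids are within 2 px vertically
   (`AmbiguousOrdering`) rather than guessing.

Detection is deterministic: identical bytes in, identical blobs out.

## Reliability statistics

Measurements are pivoted to a complete subjects × 2-conditions matrix
(conditions = occasions, raters, or instruments depending on the design;
subjects with missing cells are dropped with a logged count — listwise
deletion, no imputation; ≥ 3 complete subjects required).

* **ICC.** Default form is ICC(2,1): two-way random effects, absolute
  agreement, single measurement — appropriate when raters and occasions
  should generalize. From the ANOVA mean squares (MSR rows, MSC columns,
  MSE error):

      ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)

  The 95% CI follows the McGraw–Wong F-based formulation with
  Satterthwaite denominator degrees of freedom; bounds are clamped to
  [−1, 1] and widened to contain the point estimate when rounding would
  violate that. ICC(3,1) (two-way mixed, consistency) is available by
  config. All-identical matrices raise `ZeroVariance` rather than
  returning NaN.
* **Bands** (Koo–Li): < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90)
  good, ≥ 0.90 excellent.
* **SEM** = SD·√(1 − ICC). The SD entering the formula is configurable:
  `pooled` (default) is √(mean of the two per-condition variances);
  `baseline` uses the first condition only; `all_values` the flattened
  matrix. The pooled default best reproduces the published values this
  workflow is modelled on.
* **MDC95** = 1.96·√2·SEM, so MDC95/SEM = 2.7718… is an exact identity of
  every report.
* **CV%** = SD/mean·100 per condition, reported per condition and as
  their arithmetic mean. Requires positive condition means.
* **Pearson r** with a two-sided p from the t-transform
  (t = r·√((n−2)/(1−r²))); banding on |r|: > 0.70 strong, [0.50, 0.70]
  moderate, < 0.30 low, and the conventionally unnamed [0.30, 0.50) gap
  is tagged `unclassified`. p-values are reported, never used as gates;
  no multiple-testing correction is applied.
* **Bland–Altman.** Differences d = x − y; bias = mean(d); 95% limits of
  agreement = bias ± 1.96·SD(d) (sample SD, n−1); the per-subject
  (mean, difference) pairs are exported for plotting; the
  between-instrument SEM is SD(d)/√2.

## Synthetic data

Real validation photographs are rarely shareable, so both pipeline halves
are tested against generators that are pure functions of spec + seed.

**Scenes.** `render_scene` draws anti-aliased discs (linear edge model:
coverage = clip(r + 0.5 − dist, 0, 1)) on a plain gray or vertical-gradient
background, composites optional distractors (skin-tone discs,
clothing-colored bars — adversarial but desaturated or elongated, so the
filters must do real work), adds Gaussian pixel noise (σ on the 0–1 scale,
≤ 0.25), and optionally round-trips through JPEG at a configurable quality.
`scene_for_angle` places the patella vertex and sends the two rays at
bearings ±(180 − θ)/2 about the vertical, so the truth angle equals θ to
machine precision and the top-to-bottom ordering invariant holds for
θ > 10°. What the renderer does **not** emulate: real anatomy, lighting
gradients across a limb, motion blur, lens distortion, or marker occlusion
by clothing — passing closure tests therefore demonstrates the
detector/geometry chain is correct and noise-tolerant, not that it is
validated on human photographs.

**Tables.** `simulate_table` draws Y[i,j] = μ + s_i + c_j + e_ij with
independent zero-mean Gaussian subject, condition and error effects — the
two-way random-effects model under which the population
ICC(2,1) = σs²/(σs² + σc² + σe²). Gaussian is the standard assumption
behind the ICC ANOVA; swap the generator if you need heavy tails.
Defaults are the validation-study conditions: 42 subjects × 2 conditions,
grand mean 158.54°, total SD 5.22°, decomposed as σs = 5.04°, σc = 0.5°
(a small systematic occasion shift, consistent with the ~1° mean shifts
published cohorts show), σe = 1.26°, implying ICC ≈ 0.933.
`icc_to_variances` inverts the decomposition for any target ICC.

## Problem sizes used in the test suite

Monte-Carlo checks run at the study scale (42 × 2) with 500 replicates per
target ICC (estimator bias < 0.005, CI coverage ≈ 95%); pipeline-closure
checks render 100 noisy + 5 clean 800×1200 scenes across θ ∈ {90, 120,
150, 158.54, 175}° (max error < 0.01° noisy at σ = 5/255, < 0.005° clean,
against tolerances of 1.0° and 0.05°); Bland–Altman coverage uses 10,000
Gaussian pairs. Larger runs reproduce the same numbers; these sizes keep
the full suite under two minutes.

## Known limitations

* Angle accuracy on real photographs is bounded by marker placement, not
  by detection: the synthetic results say nothing about palpation error.
* Only three-landmark, two-condition designs are supported (no 3+-rater
  ICC, no regression-based limits of agreement).
* The detector assumes saturated markers; markerless pose estimation is
  out of scope.
* Hip and ankle frontal-plane angles, and angle-over-time curves from
  video, are out of scope.
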
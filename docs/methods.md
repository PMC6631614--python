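# Methods

`cocoonsort` implements the software half of an automated silkworm-cocoon
gender sorter: a cocoon is imaged in silhouette against a backlight, weighed
on a 0.01 g load cell, and classified male/female from the fused
weight + shape evidence. This note records the model, the conventions that
matter for reproducibility, and the limits of what the synthetic evaluation
shows.

## Why weight + shape

Female cocoons are heavier and bulkier than males of the same breed; weight
ranges per gender are breed-specific (Pure Mysore: male 0.8–1.1 g, female
1.2–1.4 g; CSR2: male 0.7–1.4 g, female 1.5–2.0 g). For Pure Mysore the
printed gender supports do not overlap, so weight alone linearly separates
the genders; silhouette size and shape carry complementary evidence and make
the decision robust where weights overlap. Backlighting matters because the
fibrous floss around the shell is translucent: lit from behind, the rigid
shell appears nearly black while floss strands stay much brighter, so a
global threshold isolates the shell.

## Pipeline

1. **Segmentation.** Otsu's method on the 256-bin histogram chooses the
   level `t` maximizing between-class variance of `{≤t}` vs `{>t}`; ties
   break toward the smaller level. Foreground is the dark side (`≤ t`).
   Connected components use 8-connectivity (4-connectivity would split thin
   silhouette necks); components under 10 px are discarded as floss specks.
2. **Single-cocoon gate.** Total foreground area must fall in a band that a
   single cocoon occupies — 500–550 px at the reference camera geometry
   (18 cm standoff), the package default. Above the band the frame is
   rejected as containing multiple cocoons, below it as empty. The band is
   camera-specific, so `calibrate_area_gate` re-derives it as mean ± 3 sd of
   a reference batch of known singletons; `run_experiment` uses this
   calibrated band so that borderline gate rejections do not contaminate the
   classifier evaluation. Gating on *total* area (not the largest
   component) matches the hardware's eject-on-excess behaviour; a
   largest-component mode is available.
3. **Shape features.** From the accepted region: area `A` (pixel count),
   perimeter `P` (count of region pixels with a 4-neighbour outside),
   moment-ellipse axis lengths λ1 ≥ λ2 (4·√eigenvalue of the central
   second-moment matrix with the +1/12 per-pixel correction, so an isolated
   pixel has finite extent), aspect ratio `E = Lb/Wb` of the minimum-area
   rotated bounding rectangle, circularity `C = A/P²`, rectangularity
   `R = A/Ar`, solidity `S = A/H`, and convexity `AC` = hull perimeter / `P`.
4. **Fusion + normalization.** The integrated feature vector is the ordered
   nine-tuple `(W, A, P, λ1/λ2, E, C, R, S, AC)` with `W` in grams. Each
   component is z-scored with mean/sd fitted on the **training split only**
   (population sd, denominator n); fitting on all data would leak test
   statistics into a deployed model. A zero-variance feature is a hard
   error, never silently dropped.
5. **Classifier.** Soft-margin linear SVM (½‖w‖² + C·Σ hinge) on the
   normalized vectors; label 1 = male, 0 = female; a decision value of
   exactly 0 maps to female (pinned tie rule). Default `C = 1.0`; the
   solver contract is the objective (verified in tests against an
   independent QP solve), not a particular algorithm.
6. **Evaluation.** Single stratified hold-out: per gender,
   `floor(0.6·n)` records train, the rest test — the only rounding
   consistent with the documented per-breed split sizes (28/26/19/18 for
   CSR2's 47♂/44♀; 21/24/14/17 for Pure Mysore's 35♂/41♀). Metrics follow
   the sorting nomenclature: TMR/TFR are per-class recalls, MPV/FPV
   per-class precisions (the legacy name "FPR" for FPV is *not* the
   false-positive rate), F1 is the male-class harmonic mean. Ratios with a
   zero denominator are reported as NaN with an `undefined` flag.
   Repeatability over k trials is the fraction of specimens classified
   *correctly in every trial*; for a deterministic pipeline this equals test
   accuracy, and it reaches 1.0 exactly when the run is error-free.

## Pixel-geometry conventions

A pixel `(r, c)` occupies the unit square centred on its coordinates. The
minimum-area rectangle is computed (rotating-calipers via the convex hull)
over the four corners of every boundary pixel, so the rectangle contains
the full region and `R ≤ 1` always. The convex hull *area* `H` is the
convex-image pixel count: the number of pixel centers covered by the hull
polygon of the boundary-pixel centers. This keeps `A ≤ H` (solidity in
`(0, 1]`, equal to ~1 for convex digital shapes) and matches the
convex-image convention of standard region-properties tools. The hull
*perimeter* used by `AC` is the Euclidean length of that hull polygon.

Perimeter-as-pixel-count is the fidelity choice, with a consequence worth
knowing: a digital disc of radius r has ≈ 4√2·r boundary pixels, so its
circularity `A/P²` converges to π/32 ≈ 0.0982, not the continuum 1/(4π).
A Crofton-formula Euclidean perimeter (`method="euclidean"`) is available
and recovers 1/(4π) on discs; the default everywhere is the pixel count.

## Synthetic specimens

No cocoon image/weight dataset is publicly deposited, so the generator
produces the study conditions the evaluation assumes:

* **Weights** uniform over the breed-and-gender range (only ranges are
  documented), quantized to 0.01 g; a truncated-normal option exists for
  overlap experiments.
* **Silhouettes**: superellipse (exponent 2.5, semi-axes 16 × 10 px at unit
  scale ⇒ ~541 px area, inside the 500–550 px gate band), with a cosine
  waist pinch uniform in [0, 0.25] and low-order radial harmonics
  (orders 3–5, amplitude sd 2%) because real shells are waisted and lumpy —
  this also gives solidity/convexity genuine between-specimen variance.
  Gender enters through the size scale: male 0.975 vs female 0.995
  (mean areas ≈ 514 vs 535 px, females larger), scale noise sd 0.5%.
* **Imaging**: background ≈ 230, shell ≈ 25 (8-bit, backlit); floss strands
  as 1 px random walks at intensity 160 — strictly between shell and
  backlight but close enough to the backlight that Otsu's bimodal split
  assigns them to background (at the midpoint intensity they would tip into
  the foreground); additive Gaussian sensor noise (sd 6 by default).
* One seed drives everything; fixed seed ⇒ bit-identical batches.

What this does **not** emulate: perspective/optics, shadows and uneven
illumination, floss that occludes the shell outline, deformed or stained
cocoons, weight–size correlation within a gender. Passing synthetic tests
therefore demonstrates that the algorithmic chain is correct and recovers
known structure — not that the headline accuracies would transfer to a
physical sorter.

## Numerical and protocol choices

* Otsu ties break toward the smaller level; the 255 split (empty upper
  class) is never a valid result; constant images are an error.
* Weight quantization clips to the configured range so rounding cannot step
  outside the documented support.
* `reconstruct_confusion_from_rates` inverts printed per-class rates to the
  unique integer confusion matrix at the given class sizes, matching to
  5·10⁻⁴ (printed rates are sometimes truncated rather than rounded, e.g.
  27/28 = 0.96428… printed as 0.9642; candidates are ≥ 1/n ≈ 0.03 apart so
  the inversion stays unique).
* Experiment problem sizes mirror the documented per-breed batches
  (47♂/44♀ and 35♂/41♀ at 64×64 px frames); a full experiment runs in
  under a second, so no further scaling is needed.
* Separable-recovery runs use `C = 10⁴` (a near-hard margin on separable
  data); the direction-recovery property test uses `C = 0.01`, where many
  in-margin points average out noise and the learned normal aligns with the
  true separating direction.

## Known limitations

* The published accuracies on real cocoons cannot be reproduced bit-for-bit
  (no deposited data, unreported SVM hyper-parameters/seed); the package
  instead verifies the printed arithmetic exactly and the method's behaviour
  on synthetic batches with the documented statistics.
* The gate defaults (500–550 px) are only meaningful at the reference
  camera geometry; recalibrate for any other setup.
* `E` (bounding-box aspect ratio ≥ 1) is deliberately *not* the classical
  ellipse eccentricity in [0, 1); the field name is kept.
* `AC` is a perimeter ratio ("convexity") despite its legacy name "convex
  area"; the formula, not the name, is implemented.
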
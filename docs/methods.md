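# Methods

## Model and assumptions

The analysis treats an eye after nontoric-monofocal-IOL cataract surgery as
an optical system whose only astigmatic element is the cornea. Under that
assumption the postoperative manifest refractive astigmatism, propagated
from the spectacle to the corneal plane, equals the total corneal
astigmatism, so the per-eye prediction error

    error = actual − predicted   (in doubled-angle space)

measures how well a given keratometry zone, combined with a posterior-cornea
model (and, on the preoperative path, a surgically-induced-astigmatism
term), anticipates the refractive outcome.

All astigmatism algebra happens in the doubled-angle plane
(x, y) = (C·cos 2θ, C·sin 2θ). This is the only representation in which
astigmatisms compose linearly; magnitudes @ axes are recovered only for
display. Left-eye axes are mirrored (θ → 180° − θ) before any pooling, so
that nasal and temporal meridians are anatomically aligned across eyes;
mirroring negates the y-component and preserves x, and is undone nowhere —
all cohort statistics live in the mirrored (right-eye canonical) frame.

Assumptions worth stating explicitly:

* **Vertex transform.** Spectacle ↔ corneal plane conversion applies
  P → P/(1 ∓ d·P) per principal meridian with vertex distance d = 12 mm by
  default (configurable). Axes are unchanged by the transform.
* **SIA as a cohort centroid.** The incision's systematic effect is the
  vector mean of per-eye preop→postop keratometric change; it is applied as
  one centroid per zone, not per eye. Random measurement noise cancels in
  the centroid but per-eye SIA variability does not enter the prediction.
* **Posterior cornea is a named substitution.** Three models ship: `zero`
  (no adjustment), `fixed_atr` (a constant, default 0.30 D steep at 180°,
  i.e. (+0.30, 0) in doubled space — the literature-consensus net
  against-the-rule behaviour of the posterior surface at the total-power
  level), and `proportional` (magnitude = s × anterior, default s = 0.3,
  orientation co-axial with the anterior meridian unless fixed). The
  defaults are package choices, not fitted values, and no equivalence with
  any proprietary toric calculator is claimed; every report names the model
  used.
* **Independence of eyes.** Two eyes of one patient are treated as
  independent observations, and p-values are not corrected for multiple
  testing; both choices mirror common practice in this literature and are
  flagged in the report footnote.

## Statistics

* **Centroid summary.** Component means and sample SDs (n−1); the centroid
  is the vector mean reported as magnitude @ axis; "centroid ± SD" uses
  SD = √(sd_x² + sd_y²), which is the definition consistent with how such
  summaries are printed alongside component SDs in the outcome literature.
  The mean absolute error is the mean of |error| and always ≥ the centroid
  magnitude.
* **Confidence ellipses.** Eigendecomposition of the 2×2 sample covariance;
  dataset ellipse semi-axes √(q·λᵢ) with q = χ²₂(0.95) = 5.991; centroid
  ellipse semi-axes √(q·λᵢ/n). The exact small-sample Hotelling-T² F
  scaling is available (`scaling="hotelling"`); at n ≈ 100 it widens the
  ellipse by < 5%, and the χ² convention matches the widely used
  double-angle plotting tools. Rank-deficient covariances yield a flagged
  degenerate ellipse (semi-minor 0) rather than an error.
* **Paired zone comparison.** Two-sided paired t tests on the x components,
  y components and magnitudes of the per-eye differences (2.4 mm − 3.3 mm).
  Zero within-pair variance is resolved deterministically: p = 1 when the
  constant difference is 0, else p = 0.
* **Subtype classification.** WTR = [60°, 120°] (closed), ATR = [0°, 30°) ∪
  (150°, 180°), oblique = the rest, so every axis gets exactly one label
  (over integer axes 0–179: 61/59/60). The shared endpoints are a
  convention of this package: WTR keeps its endpoints because the class is
  centred on 90°. Zero-magnitude astigmatism has no meaningful class; it is
  labelled by its canonical 0° axis and flagged so reports can drop it.
  Subgroup labels come from the preoperative keratometric axis *at the zone
  under analysis*; when the zones disagree, each zone uses its own label
  and the discordance count is logged. Within-subtype between-zone paired
  tests use the eyes whose labels agree in both zones.
* **Regression.** Ordinary least squares of a chosen error response
  (|error|, x or y) on age, sex (0 = M, 1 = F), axial length, IOL power,
  preoperative astigmatism magnitude and corneal irregularity; univariate
  and multivariate modes; a condition number above 10⁸ adds a collinearity
  warning to the report.

## The synthetic cohort generator

No per-eye data accompany retrospective chart studies, so the generator
produces cohorts with the structure this analysis assumes, plus a
ground-truth sidecar (true anterior/posterior astigmatism, per-eye SIA,
true total refractive astigmatism, subtype) that the analysis path never
reads.

Defaults describe a realistic elderly cataract cohort: n = 101 eyes; age
68.7 ± 9.3 y truncated to [47, 89]; axial length 24.7 ± 2.0 mm in
[21.86, 30.25]; IOL power 18.1 ± 5.2 D in [6, 27.5]; 52.5% male; 44.6% left
eyes; subtype mixture 46.5% WTR / 32.7% ATR / 20.8% oblique with
wrapped-normal axis scatter (SD 12°) about the class centres (90°; 0°≡180°;
45° or 135° split evenly — the doubled-angle geometry makes these centroids
analytically known); corneal astigmatism magnitude 0.7 ± 0.5 D truncated to
[0.05, 2.05]; flat keratometry level 43.57 ± 1.5 D. An eye's subtype label
is the classification of its realised axis (the latent mixture component is
stored separately), so subtype-specific biases and subgroup recovery are
exact by construction in the noiseless limit.

Systematics and noise:

* **Zone offset.** The 2.4-mm zone reads the mean keratometry steeper than
  the 3.3-mm zone by 0.04 D preoperatively and 0.08 D postoperatively
  (prolate cornea), with the postoperative level shifted +0.12 D.
* **SIA.** A 2.65-mm clear corneal incision at 145° flattens its own
  meridian, so the systematic SIA is 0.10 D steep at 55°
  (doubled-angle (−0.034, +0.094)); per-eye SIA scatters around it with
  0.25 D per-component SD. Both numbers are package choices — per-eye SIA
  statistics are rarely published — and are deliberately small.
* **Measurement noise.** Keratometric astigmatism noise 0.20 D and manifest
  refraction noise 0.45 D per doubled-angle component, chosen once so that
  the closed-loop prediction-error component SDs land near the ~0.49–0.51 D
  dispersion typical of published dual-zone cohorts
  (√(0.20² + 0.45²) = 0.49); mean-K level noise 0.05 D. The refraction
  noise proxies subjective-refraction granularity plus IOL tilt and
  decentration.

Draw order is fixed (one eye at a time, fields in documented order) with a
single `numpy` default RNG, so a seed determines the cohort bit-for-bit.
Left eyes are stored with real-world (unmirrored) axes; the analysis-side
mirror restores the canonical frame in which all truth fields are recorded.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: paired eyes of one patient (every eye gets its own
patient ID), non-Gaussian refraction error (real manifest refraction is
quantised to 0.25 D steps), axis-dependent measurement noise, dry-eye or
tear-film instability, the BCVA/complication exclusion pathway (the
generator emits only analysis-eligible eyes; filters are tested on
hand-flagged fixtures), and any genuine between-zone difference in
predictive accuracy — the generator is calibrated to a *null* zone effect,
so it validates calibration and recovery, not the clinical finding itself.

## Numerical choices

* Axes are canonicalised to [0, 180) with 180 → 0; the zero vector maps to
  0 D @ 0°.
* Error sign convention: actual − predicted (positive x = the outcome is
  more ATR-steep than predicted / under-prediction along +x). Paired
  comparisons are invariant to a global flip.
* Round-trip tolerances: polar ↔ doubled-angle conversions are verified to
  1e−9 D in magnitude and 1e−7° in axis; closed-loop (noiseless) prediction
  errors to 1e−9 D — the vertex transform is an exact analytic inverse and
  leaves only float rounding.
* Cohort CSVs store numerics at 6 decimal places; figures render from the
  saved per-eye error CSV (9 decimals) so that re-rendering from disk is
  byte-identical; SVGs carry a fixed hash salt and no timestamp.
* Monte-Carlo problem sizes in the test suite — 2000 replicates of n = 101
  for ellipse coverage, 1000 replicates for paired-t calibration, n = 1000
  for parameter recovery, 10⁴ draws for the loop-oracle comparisons — were
  chosen to give binomial/standard-error bands an order of magnitude
  tighter than the asserted tolerances while keeping the default suite
  under a minute of Monte-Carlo time.

## Known limitations

* Absolute centroid values from clinical studies are not reproducible here:
  they depend on a proprietary posterior-cornea calculator and undeposited
  per-eye data. The package's claims are therefore structural (calibration,
  recovery, exactness), not numerical reproduction.
* The `proportional` posterior model applied on the postop path uses the
  postoperative anterior meridian, while a generator's true posterior is
  fixed preoperatively; with a nonzero SIA this induces a small, realistic
  model error rather than an exact cancellation.
* No mixed-effects handling of fellow eyes and no multiple-testing
  correction (deliberate, to match field practice); both would be
  straightforward extensions.
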
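# Methods

## Measurement model

The package models a UV-reflectance photograph as an 8-bit intensity
grid in which bare skin reflects at a participant-specific level and
skin carrying a UV-absorbing product is darker. Two assumptions drive
the design:

* **Darkening is relative, not absolute.** Baseline skin intensity
  varies strongly with skin tone (Fitzpatrick I–IV), so the
  covered/uncovered decision threshold is calibrated per participant
  from the bare-skin baseline image: `T = max(mu − k·sigma, floor)`.
  With Gaussian sensor noise, `k = 3` fixes the false-covered rate on
  bare skin at the normal tail `P(Z < −3) ≈ 0.13%` per pixel. `k`,
  `floor`, and both morphology parameters are configuration values.
* **Product is dark, never bright.** A pixel is covered iff its
  working-channel intensity is strictly below `T`. Grayscale input
  passes through; RGB input is converted by the standard hexcone HSV
  transform and the value channel used, with an optional saturation
  band gate for cameras that leave a colour cast. The conversion is
  checked pixelwise against an independent HSV implementation in the
  tests.

Segmentation cleanup defaults are deliberately minimal: morphological
closing of the covered mask with a radius-1 disc (fills pinhole gaps)
followed by removal of covered components smaller than 5 px (drops
noise specks). Both can be disabled (`close_radius=0`, `min_blob=0`).

Baseline images whose covered fraction under a provisional global
threshold exceeds 5% are flagged (`baseline_contamination_flag`):
participants sometimes arrive already wearing an SPF product, and
calibrating on such a baseline would mask real coverage. The flag
requires an operator decision; the pipeline does not guess.

## Regions

Regions are axis-aligned boxes derived from the standard 68-point
landmark scheme (half-open `[x0,x1)×[y0,y1)` boxes, 0-based pixel
coordinates, origin top-left; "left/right" are image-frame, not
anatomical — stated in every report header). The face box runs between
the outermost jaw points and from an extrapolated forehead line (brow
top minus `forehead_margin` × eye-to-brow distance, default 1.0) to the
chin point. Eyelid boxes are each eye's bounding box raised to the brow
line and widened by 10% of eye width. Canthus boxes are squares of side
`min(0.60 × inter-inner-corner distance, 0.25 × eye width)` centred on
the inner eye corner and shifted nasally by 25% of the side. No
standard landmark convention exists for these boxes, so every margin
is a parameter and the derivation is recorded in the `RegionSet`
provenance. Box edges rasterize by rounding to the nearest pixel
boundary, which keeps region areas unbiased under rescaling of the
geometry; for boxes a few tens of pixels across, ±1 px per edge of
discretization still dominates relative-area comparisons, and the
scale-equivariance test budgets for it explicitly.

The half-face split used by the dose-response measurement divides the
face mask at the mean x of the four nose-bridge points; the two halves
partition the face mask exactly.

## Synthetic data: what it emulates

`generate_participant` renders a baseline image (skin tone +
independent Gaussian noise, default SD 2 grey levels), then an applied
image in which covered pixels are attenuated multiplicatively by
`a(mass) = exp(−κ·mass)` with `κ = −ln(0.6)/100` — a 100 mg-equivalent
application darkens covered skin by 40%, and darkening saturates with
mass, giving a strictly monotone dose response. Uncovered pixels stay
at skin tone; the exact uncovered set is recorded as ground truth.

Application failures are *contiguous blobs*, not i.i.d. pixels — people
repeatedly miss the same anatomical areas — placed with extra weight
inside the medial-canthus boxes. Per-region missed fractions are hit
exactly (to one pixel) on the eyelid/non-eyelid partition. A subtle but
load-bearing construction detail: blobs are built to be invariant under
the segmentation's own default closing step. Discs are stamped only at
radii whose rasterization survives `closing(disk(1))` unchanged
(radius ≥ 3.2, so a single noise-flipped interior pixel is healed by
the small-component filter rather than cascading), separated by
one-pixel gaps to avoid thin tangency necks, and the exact-count
remainder accretes only at positions that keep every pixel stable under
the closing (pixel survival is a local plus-shaped test and is monotone
in the set, so stability never regresses). Without this, the cleanup
step systematically ate 1–3 percentage points of ground truth in the
narrow eyelid boxes and recovery experiments conflated segmentation
error with generator artefacts. The residual gap between truth and an
ideal segmentation is at most a few pixels per region (the sub-5-pixel
tail of an exact count).

`generate_population` draws paired per-region percent-missed values
from a bivariate normal — sunscreen and moisturiser components
correlated at `rho = 0.5` within participant — truncated to [0, 100] by
clipping. Defaults are the conditions of an 84-participant crossover
study: face 11.1 (SD 5.0) vs 16.6 (SD 6.4), eyelid 14.0 (SD 8.3) vs
20.9 (SD 8.2), non-eyelid 9.5 (SD 5.5) vs 13.6 (SD 6.9) percent missed
for sunscreen vs moisturiser; mean-centred additive subgroup shifts of
−5 pp for males and −6 pp for skin types III+IV (magnitudes consistent
with the reported subgroup contrasts, centred so marginal means are
preserved); a 62:22 female:male ratio; skin-type probabilities
(0.30, 0.45, 0.15, 0.10) for I–IV; ages uniform on 18–57; a 60:24
first-formulation split (scaled proportionally for other n); and a
per-visit medial-canthus miss probability of 0.78. The applied-mass
defaults (100 mg-equivalent sunscreen, 75 moisturiser) encode the
observation that less moisturiser tends to be applied.

One deliberate inconsistency is documented rather than hidden: the
face-level and region-level default means are mutually consistent only
if the eyelid holds ~36–41% of the face-box pixels, whereas a
landmark-derived eyelid box plausibly holds ~11%. The image generator
therefore takes the eyelid and non-eyelid draws as truth, and the
*measured* face percent is the pixel-weighted identity value
(≈10.3% / 14.4% at the defaults), not the face-level default numbers;
the population table still carries face-level draws at those defaults
for analyses that work on the table directly.

What the generator does **not** emulate: photorealistic faces,
illumination gradients, shadows, specular highlights, off-frontal pose,
landmark-detector failure modes, or any UV-B/SPF protection model.
Noise is i.i.d. Gaussian because the source studies do not characterize
their sensor noise; the level is a stated assumption exposed as a
parameter. Passing tests therefore demonstrate correctness of the
measurement and analysis chain under the stated image model — not
robustness to real-world photographic nuisance.

## Statistics

* **Normality gate.** Kolmogorov–Smirnov with the Lilliefors correction
  (parameters estimated from the sample; the naive KS test in this
  situation is badly anti-conservative), α = 0.05. On rejection, log
  then sqrt transforms are tried — samples are shifted positive first
  when needed and the shift is recorded — before routing nonparametric.
  Constant samples route nonparametric with a degenerate warning;
  samples below the Lilliefors minimum (n < 4) are assumed parametric
  with a warning.
* **Paired comparison.** Two-sided paired *t* on the (possibly
  transformed) values; the nonparametric fallback defaults to the
  Mann–Whitney U on the two samples, with a Wilcoxon signed-rank
  alternative behind a configuration switch. Using an unpaired test
  inside a paired design is questionable, but it is the documented
  fallback of the analysis plan this module reproduces; the audit trail
  records which test ran, and neither option is asserted as correct.
  All-zero difference vectors return t = 0, p = 1 rather than NaN.
* **Repeated-measures ANOVA.** One within factor, computed directly
  from within-subject sums of squares. This guarantees the exact
  algebraic identity F = t² for two-level designs (asserted to 1e-9)
  and is fast enough for 2000-replicate calibration experiments;
  statsmodels' AnovaRM is the independent oracle in the test suite.
  Incomplete subjects raise an error naming the participants.
* **Subgroups.** One-way ANOVA across group × formulation cells, then
  between-group contrasts within each formulation, Šidák-adjusted with
  m = family size. `p_adj = 1 − (1−p)^m ≥ p` always.
* **ANCOVA.** OLS of `percent_missed ~ C(sex) * C(skin_group) + age`
  with Type II sums of squares by default (Type III available); Type II
  is the better default for the near-balanced synthetic designs this
  package generates. Rank-deficient designs raise rather than
  silently dropping terms. Skin types collapse deterministically to
  {I+II, III+IV}.
* **Dose response.** `mean_intensity ~ mass × formulation`; reports
  per-formulation slopes (grey levels per mg; the non-reference slope's
  SE uses the full parameter covariance) and the joint F for any
  formulation effect against the mass-only model. A perfect shared-line
  fit (zero residual) returns F = 0, p = 1 instead of 0/0.
* **Binary tabulation.** Display percentages truncate the fraction
  (66 of 84 reads as 78%) to match the convention used when such counts
  are reported; the exact value is retained alongside.

All tests run at α = 0.05. Summaries print percentages to one decimal;
CSVs keep full precision.

## Determinism and problem sizes

Every generator output is a pure function of (spec, seed); pipeline
runs with a fixed seed and configuration produce byte-identical CSVs
(timestamps are excluded by design, and the configuration is echoed
into every output directory). Simulation-based checks in the test suite
use sizes chosen to make Monte-Carlo error small relative to the margin
being asserted: 84 participants (the study scale) for calibration and
power, 2000 replicates for type-I error, 200 for power and population
means, 20 seeds × 4 fractions for end-to-end recovery, 128×128 images
throughout (the smallest size at which region geometry is comfortable;
64×64 is the hard floor).

## Known limitations

* Region boxes are axis-aligned rectangles; real periocular anatomy is
  not, so absolute percent-missed values depend on the chosen margins.
  Between-condition comparisons within a study are unaffected, since
  the same geometry is applied to both visits.
* The pipeline consumes landmarks; it does not detect them. An external
  detector can be adapted by writing its output as PTS or JSON.
* Percent missed is an area metric: it says nothing about application
  thickness, dose, or UV-B protection. Darkness change is a proxy for
  amount applied only within one camera/lighting setup.
* The canthus covered/missed score interprets "fully covered" as a
  covered fraction ≥ `tau = 0.95`; whether a handful of uncovered
  pixels should count as missed is a judgement call, so `tau` is
  exposed.
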
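# Methods

## Coordinate and calibration conventions

Pixel coordinates are 0-based `(col, row)` with the pixel center at integer
coordinates; row 0 is the shallowest tissue. Physical positions are
`(col·Δx, row·Δy)` in cm. DICOM `PixelSpacing` is `(row, col)` in mm and is
converted to cm on read; an explicit spacing override always wins over the
tags, because point-of-care devices frequently carry absent or wrong
calibration. 16-bit frames are kept at native depth; only the grayscale
statistics rescale, linearly by the full representable range
(`0 → 0`, `2^depth − 1 → 255`), never by the observed min/max, so absolute
echogenicity remains comparable across images.

## Rasterization

A pixel is labelled iff its center lies inside the ROI polygon or exactly
on its boundary (shapely `intersects`). If the rasterization fragments into
several 4-connected components (possible for thin slivers crossing the grid
diagonally), only the largest is kept. This rule is deliberately simple so
that an independent brute-force point-in-polygon enumeration reproduces the
mask exactly, which the test suite checks on random polygons. A polygon
whose interior contains no pixel center is a degenerate-ROI error rather
than an empty measurement.

## Metrics

- **Area**: labelled-pixel count × pixel area. No boundary-fraction
  correction is applied; at the 0.01 cm/px working resolution the
  discretization error on a ≈3.5 cm² ellipse is ~0.2%.
- **Classic X/Y axes**: bounding extents `(max−min)` of labelled columns
  and rows, scaled by the spacings. The caliper placement these emulate is
  not formally defined anywhere, so bounding extents (rather than chords
  through the centroid) were chosen; for convex cross-sections the two
  coincide.
- **Principal axes**: the population covariance of the labelled pixel
  *physical* coordinates is eigen-decomposed (physical, so anisotropic
  spacing is handled). Eigenvalues are sorted descending; each eigenvector
  is sign-fixed to a non-negative image-x component; if the eigenvalues tie
  to within 1e-9 relative (a circular mask), the axes fall back to the
  image axes with the first along x. Eigen-extents are raw max−min spans of
  the projections — no pixel-diagonal correction — so for a uniform ellipse
  they estimate the full diameters 2a and 2b, and the eigenvalues estimate
  a²/4 and b²/4.
- **Overflow**: true iff any labelled pixel lies within 2 px of the left or
  right border. Depth (top/bottom) contact never triggers the flag: the
  clinical constraint is transducer *width*, and lateral truncation is what
  makes the marked area an underestimate.
- **Replicate averaging**: numeric metrics are averaged arithmetically
  across consecutive acquisitions; the overflow flag is OR-combined, since
  one truncated replicate already biases the averaged area; averaged
  eigenvector frames are re-orthonormalized by QR.

No smoothing or speckle filtering is applied before measurement; the tool
measures exactly the pixels the operator marked.

## Outcome coding and normalization

Height normalization divides a metric by stature squared (m²), mirroring
the skeletal-muscle-index convention. The composite outcome is: good iff
stay ≤ 5 days *and* home discharge; poor iff stay ≥ 10 days *or* any
non-home discharge (home hospitalisation, social-health-centre referral,
death), the destination clause taking precedence so that a short stay
ending in death is not coded good; home discharges with 6–9-day stays are
excluded as logistics-confounded. The boundary is ≤ 5 (not < 5): the two
phrasings conflict in the source clinical protocol and the group count
table is only consistent with ≤ 5. GLIM malnutrition OR-combines the
phenotypic criteria (>5% six-month weight loss; BMI < 20 under 70 y or
< 22 at 70+; reduced muscle mass by BIA), with the etiologic criterion
assumed satisfied in a surgical-oncology population; whether the source
protocol required the muscle-mass criterion specifically is ambiguous, and
the OR reading is flagged as an assumption. Missing covariates exclude a
subject from the affected analysis only (complete-case per analysis).

## Statistics

- **Correlation CI**: Fisher z, `tanh(atanh r ± z_{0.975}/√(n−3))`; the
  p-value is the usual t-test on `r√((n−2)/(1−r²))`. The Fisher method
  reproduces the published US-X and US-Y interval rows exactly at two
  decimals; the US-area row computes (0.58, 0.75) against a printed
  (0.57, 0.74), consistent with the printed r itself being rounded.
- **Normality gate**: Anderson–Darling with estimated mean and SD (ddof 1),
  computed from the order-statistic formula directly, adjusted by
  `(1 + 0.75/n + 2.25/n²)` and compared to the 0.752 critical value
  (α = 0.05). The unadjusted statistic is cross-checked against
  scipy.stats.anderson in the tests.
- **Variance gate**: classic mean-centered Levene with an F(1, N−2)
  reference.
- **Location test**: pooled-variance Student t when both groups pass the
  normality gate and Levene accepts equal variances (the gate justifies
  pooling); otherwise two-sided Mann–Whitney U. For pooled n ≤ 12 the
  Mann–Whitney p is exact: all C(n₁+n₂, n₁) labelings of the pooled
  midranks are enumerated and p = P(min(U₁,U₂) ≤ observed min), which with
  ties is the exact permutation test on midranks. Above that, scipy's
  asymptotic method with tie and continuity correction.
- **ROC**: AUC via the rank (Mann–Whitney) formula, identical to pairwise
  counting with half credit for ties; positive class is the good outcome.
  SE by Hanley–McNeil. Subjects in the excluded outcome band take part in
  neither the test nor the ROC.
- α = 0.05 throughout; no multiple-testing correction across the metric ×
  normalization × overflow-policy grid — a deliberate mirror of the
  clinical workflow and a documented limitation.

## Synthetic data

The phantom draws an ellipse of muscle-gray speckle on a brighter
background (defaults: a = 1.5, b = 0.75 cm, 600×400 px at 0.01 cm/px,
muscle gray 90, background 170, multiplicative log-normal speckle with
CV 0.3, unit mean). The ROI handed to the pipeline is a 64-vertex polygon
tracing the (clipped) ellipse boundary; ground-truth area for clipped cases
comes from a 4096-vertex polygon intersected with the frame rectangle,
accurate to O((2π/4096)³) — chosen over grid oversampling as it is exact up
to boundary discretization and far cheaper. Overflow ground truth is
lateral clipping by construction.

The cohort simulator encodes the study conditions the analysis was built
for: 111 good / 32 poor outcomes; the evaluated metric ~ Normal(4.06, 1.35)
vs Normal(3.45, 1.35) cm² truncated at 0 (by redraw, preserving the density
shape); stature ~ Normal(1.65, 0.09) m clipped to (1.4, 2.1) — a typical
elderly European surgical cohort, as no stature distribution is published;
overflow ~ Bernoulli(0.62); stays of 2–5 days (uniform integers) for good
outcomes; poor outcomes are non-home discharges with probability 0.44
(stay unconstrained, exponential mean 8 d) or home discharges at
10 + ⌊Exp(12.35)⌋ days, targeting the published ≥10-day group mean of
≈22 ± 15 d; a CT reference column with mean 112.59, SD 28.52 cm² and
target pooled correlation r = 0.67, constructed by mixing the
mixture-standardized metric with independent noise.

What the simulator does *not* emulate: real segmentation uncertainty
(the ROI is given, so only rasterization noise applies), inter-operator
marking variability, attenuation/shadowing artefacts, correlation between
overflow and muscle size (in real data larger muscles overflow more), or
non-Gaussian metric distributions. Passing tests therefore validate the
measurement and statistical machinery, not the clinical effect sizes.

## Problem sizes

Validation runs use what one CPU core handles in seconds: 600×400-px
phantoms, cohorts of 143–1000 subjects, 500-replicate AUC closure and
1000-replicate type-I simulations, and enumeration oracles at n ≤ 50
(ROC) / pooled n ≤ 12 (Mann–Whitney exact).

## Known limitations

- The exact Mann–Whitney branch is factorially bounded and refuses pooled
  n > 12 by design.
- The Anderson–Darling gate uses the fixed α = 0.05 critical value 0.752;
  other levels would need the corresponding constants.
- The eigen-extent of a strongly non-convex mask can in principle be larger
  along the minor-variance axis; extents are reported as projected on the
  variance-ordered axes regardless.
- DICOM support covers single-frame grayscale only (no cine loops, Doppler,
  or multi-frame objects).
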
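# echomorph

Semi-automated morphometry of muscle ultrasound, built around the rectus
femoris (RF) — the standard mid-thigh site for bedside assessment of muscle
mass in sarcopenia and malnutrition work-ups — together with the statistical
workflow used to judge whether such measurements separate patients with good
and poor clinical outcomes.

## What it computes

Given one calibrated transverse ultrasound frame and a manually drawn ROI
polygon around the muscle, the tool labels every pixel whose center falls
inside the polygon and derives:

- **CSA** — cross-sectional area, `n_pixels · Δx · Δy` (cm²);
- **classic X / Y axes** — axis-aligned caliper extents (lateral and
  anteroposterior, cm);
- **centroid** — mean position of the labelled pixels;
- **eigen-axes** — PCA of the labelled pixel coordinates: the first
  principal axis is the direction of highest positional variance (the long
  diameter of the muscle "ellipse"), the second is perpendicular to it.
  The extents projected onto these axes (`x_eigen`, `y_eigen`) are
  invariant to probe rotation, unlike the classic calipers;
- **echogenicity** — mean ± SD grayscale on the 0 (black) – 255 (white)
  scale; higher values suggest fatty/fibrous infiltration;
- **overflow** — a flag set when the labelled region touches the lateral
  image borders, i.e. the muscle is wider than the transducer footprint and
  the marked area underestimates the true CSA.

All metrics can be standardised by height squared (cm²/m², analogous to the
skeletal muscle index), replicate acquisitions are averaged, and a cohort
module codes the composite clinical outcome (stay ≤ 5 days + home discharge
= good; stay ≥ 10 days or non-home discharge = poor; 6–9-day home
discharges excluded) and GLIM malnutrition.

The statistics module implements the outcome-separability workflow:
Pearson correlation with Fisher-z 95% CIs against a CT reference
(skeletal muscle area at L3); a gated two-group test — Student's t (pooled)
when both groups pass an Anderson–Darling normality check and Levene's
equal-variance test, Mann–Whitney U otherwise (exact enumeration for pooled
n ≤ 12); and ROC AUC = P(score_good > score_poor) + ½·P(tie) with the
Hanley–McNeil standard error
SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₂−1)(Q₂−A²)]/(n₁n₂),
Q₁ = A/(2−A), Q₂ = 2A²/(1+A).

A phantom module renders speckle images with known ellipse geometry (the
validation oracle, including clipped/overflow cases) and simulates
two-outcome-group cohorts with configurable group means, SDs, overflow
prevalence and CT correlation.

## Worked example

Render a phantom (ellipse a = 1.5 cm, b = 0.75 cm rotated 20°, speckle
CV 0.3, muscle gray 90) and measure it:

```sh
$ echomorph simulate-phantom --seed 3 --theta-deg 20 --out-dir demo
$ echomorph measure --image demo/phantom.dcm --roi demo/phantom.roi.json
image_id,area_cm2,x_cm,y_cm,x_eigen_cm,y_eigen_cm,gray_mean,gray_sd,sub_fat_cm,overflow
phantom-seed3,3.5279,2.86,1.74,2.99879,1.49854,89.991,27.013,,False
```

The measured area 3.528 cm² recovers the analytic πab = 3.534 cm² within
0.2%; the eigen-extents (2.999, 1.499) recover the true diameters
(3.0, 1.5) despite the 20° rotation, while the classic calipers read the
rotated bounding box (2.86, 1.74) — exactly why the eigenvector metrics
exist. The interior gray mean 89.99 matches the generating value 90.

Simulate a cohort (111 good / 32 poor outcomes, CSA ~ N(4.06, 1.35) vs
N(3.45, 1.35) cm², 62% overflow) and run the analysis:

```sh
$ echomorph simulate-cohort --seed 7 --out cohort.csv
$ echomorph analyze --cohort cohort.csv --metrics area_cm2 --out report
         metric  overflow_policy  normalized  n_good  n_poor  mean_good  mean_poor      test        p      auc   auc_se
       area_cm2              all       False     111      32   3.859012   3.177672 student_t 0.005566 0.649493 0.051732
area_cm2_per_m2              all        True     111      32   1.455095   1.180518 student_t 0.005166 0.664977 0.050701
       area_cm2 exclude_overflow       False      47      15   3.841184   3.116158 student_t 0.071404 0.646809 0.077436
area_cm2_per_m2 exclude_overflow        True      47      15   1.463346   1.187906 student_t 0.080734 0.639716 0.078074
 reference   metric   n        r   ci_low  ci_high            p
ct_sma_cm2 area_cm2 143 0.657359 0.552867 0.741497 4.785205e-19
```

Both groups pass the normality/variance gate, so Student's t is used; the
AUC ≈ 0.65 sits near the Gaussian closed form
Φ(Δμ/σ√2) = Φ(0.61/1.91) ≈ 0.625 for these generating parameters, and the
simulated CT–US correlation r = 0.66 (CI 0.55–0.74) reflects the
generator's r = 0.67 target.

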
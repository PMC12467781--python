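# Methods

## Signal model of the synthetic cohorts

Each raw acquisition on the grid ν ∈ {400, 402, …, 1800} cm⁻¹ is

    I(ν) = B(ν) + Σ_k a_k · g_k · s_k · r · L(ν; c_k, w) + ε(ν)

* **B(ν)** — autofluorescence background, a degree-4 polynomial in the
  scaled coordinate ξ = (ν − 1100)/700, default coefficients
  (700, −350, 120, −60, 40): positive over the whole grid, decreasing toward
  high wavenumber as serum autofluorescence does under 785 nm excitation,
  and of the same order as the band amplitudes so that baseline removal is a
  non-trivial part of the problem.
* **L(ν; c, w)** — Lorentzian line with apex 1 at center c and HWHM w
  (default 6 cm⁻¹), the standard Raman line shape.
* **c_k, a_k** — the 14 assigned serum bands (arginine 490, cysteine 524,
  ascorbate/amide-VI 588, tyrosine 635, uracil 802, protein CH₂ 883,
  phenylalanine 1004, lipid C–C 1064, mannose 1127, tryptophan 1197,
  collagen 1323, lipid CH₃ 1379, nucleic-acid bases 1575, amide-I 1647
  cm⁻¹).  Amplitudes (40–120 counts) are a plausible serum-like profile
  with phenylalanine dominant; they are configurable and are a modelling
  choice, not measured values.
* **g_k** — group multiplier.  Sham is the all-ones reference.  OVX raises
  tyrosine (×1.35) and lowers arginine, lipids, tryptophan and collagen
  (×0.70–0.75); ICA lies strictly between Sham and OVX at every affected
  band (treatment partially restores the profile).  The directions are the
  published ones; the magnitudes are chosen so that group differences are
  clearly detectable at n = 30 per group without being trivially separable
  at the per-spectrum level.
* **s_k** — per-sample, per-band log-normal factor (σ = 0.08), shared by
  all replicates of a sample.  Making it per-band matters: a single global
  per-sample factor would be removed exactly by area normalization, leaving
  the cohort with no between-sample variance at all.
* **r** — per-replicate global log-normal factor (σ = 0.04), emulating
  drop-to-drop enhancement variation within a serum droplet.
* **ε** — i.i.d. Gaussian detector noise, σ = 3 counts.  No cosmic-ray
  spikes are simulated.

Noise and variance magnitudes are not reported for the original serum data;
the defaults above are documented modelling choices, tunable through
`SyntheticCohortConfig`, and all statements made by the test suite are
statements about cohorts generated under these settings — not about real
serum spectra, which add wavenumber calibration error, detector etaloning,
correlated (1/f) background drift and biological covariance between bands.

Seeding: one root seed; the stream for a sample is derived from
(seed, group, sample) and for a replicate from (seed, group, sample,
replicate), so any subset of the cohort is reproducible in isolation.

`generate_latent_cohort` is a separate fixture generator for
component-count studies: k + 1 classes at the vertices of a regular simplex
in a k-dimensional latent space, embedded through a random orthonormal
loading matrix into p channels with isotropic Gaussian noise.  The regular
simplex makes the between-class scatter isotropic, so all k planted factors
carry equal response variance and a cross-validated prediction-error curve
has its elbow exactly at k.

## Baseline removal

The fluorescence background is estimated by iterative modified polynomial
fitting (the Vancouver Raman Algorithm family): fit a polynomial (default
order 5), estimate the residual noise level, flag points lying more than
one noise SD above the fit as peak, replace their working values by the
fit, and repeat.  Two implementation choices deviate from the most common
textbook variant and are deliberate:

* the polynomial is fit **only to points not yet flagged as peak**, rather
  than to the peak-replaced working signal.  With 14 overlapping Lorentzian
  bands the replace-and-refit variant retains a positive bias of ≈2.5
  counts under the crowded 1000–1250 cm⁻¹ region (tail overlap), which is
  ≈6% of the weakest band; excluding flagged points reduces the worst-case
  apex error to ≈4.4%.
* convergence is declared when the fitted curve's **maximum absolute change
  relative to its dynamic range** falls below the tolerance (default
  1e−3).  An L2-relative criterion is dominated by the baseline's large
  constant offset and can halt after ~3 iterations with ~11% apex bias.

Noise is estimated as the SD of (working signal − fit) over non-flagged
points; the stripping threshold is fit + 1×noise; at most 100 iterations;
non-convergence is reported in the result, not raised.  On peak-free input
the procedure reduces to ordinary least squares (verified to < 1e−6
relative).  Negative corrected values are retained by default so that area
normalization stays linear; clipping is available as an option.

## Normalization and averaging

Spectra are divided by their trapezoidal integral over the native grid, so
processed intensities are densities per cm⁻¹ integrating to 1.  Replicates
are baseline-corrected and normalized individually, then averaged
(configurable switch): per-replicate normalization prevents one bright
acquisition from dominating a sample's mean.  Grids must match exactly; no
resampling is attempted.

## Band statistics

Band intensity is the maximum of the processed spectrum within ±5 cm⁻¹ of
the nominal position (robust to small calibration shifts, ties to the
lower wavenumber).  Group comparison follows the assumption-routed tree:
Shapiro–Wilk per group at α = 0.05; if all groups pass, Levene's test
(classic mean-centered; median-centered available) routes to one-way ANOVA
(homogeneous) or Welch's ANOVA (heterogeneous); any non-normal group routes
to Kruskal–Wallis.  The same α is used for the assumption tests and the
final significance call.  No multiple-testing correction is applied across
the 14 bands by default, matching the presentation style the pipeline
reproduces; Benjamini–Hochberg is available as an option.  RSD uses the
n−1 standard deviation.  The enhancement factor is the
concentration-normalized intensity ratio (I_SERS/c_SERS)/(I_ref/c_ref).

## PLS–SVM classification

PLS2 by NIPALS on mean-centered spectra against mean-centered one-hot
class indicators; no unit-variance scaling (all channels share the
normalized intensity scale).  Inner power loop to 1e−12 on the weight
change (max 5000 iterations); both blocks are deflated by each component's
score, so scores are orthogonal by construction.  Rank exhaustion stops
extraction early with a warning.

The component count minimises over a cross-validated MSEP curve with the
adjusted Wold's R rule: walking N = 1, 2, …, component N is kept while its
relative improvement (MSEP[N−1] − MSEP[N])/MSEP[N−1] is at least the
threshold (default 5%); the equivalent ratio form MSEP[N]/MSEP[N−1] ≤ 0.95
is provided as an option.  The curve's index 0 is the zero-component
baseline (predicting training class proportions).  The rule is floored at
one component.  Note a structural property: when prediction is nearly
perfect the MSEP floor is close to zero and cross-validation fluctuations
become large *relative* changes, so the rule can overshoot by one; the
planted-factor fixtures therefore operate at moderate signal-to-noise where
the floor is dominated by irreducible class overlap.

SVM: RBF kernel K(u,v) = exp(−‖u−v‖²/(2σ²)) (so sklearn's γ = 1/(2σ²)),
multiclass by one-vs-one majority voting with ties resolved through the
aggregated decision values.  Grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and
σ ∈ {2⁻⁴, …, 2⁴} by stratified 10-fold CV accuracy; ties prefer the
smallest C, then the smallest σ.  Grid search and the final report share
one fold structure (single-level protocol); out-of-fold predictions build
the confusion matrix, one-vs-rest sensitivity/specificity, accuracy
(trace/total) and the ROC (trapezoidal AUC) of the designated positive
class (default OVX; for the Sham-vs-ICA task, ICA).

**Leakage control.** Inside `run_pls_svm` the PLS projection is re-fit on
each CV training fold before the SVM sees any scores.  Projecting with a
supervised reduction fit on *all* samples would leak the held-out labels
into the features — with ~700 wavenumbers and 90 samples the leak is total
and a label-free cohort scores far above chance.  The fixed-feature
entry points (`grid_search_svm`, `classify_and_report`) accept any feature
matrix and are honest whenever those features were derived without labels;
`refit_pls_per_fold=False` restores the full-data projection for
comparison.  Because the reported accuracy is the best of the grid under
shared folds, it retains the usual model-selection optimism of single-level
protocols (a few points at chance level); chance-level claims should
therefore be evaluated with a fixed (C, σ) or a nested scheme.

## Problem sizes

Defaults mirror the study design: 90 samples (3 × 30), 10 replicates, 701
grid points.  The test suite uses the full cohort where a property concerns
the study scale (effect-direction power, separable-limit classification)
and smaller seeded cohorts elsewhere; the component-selection fixture uses
60 samples × 120 channels with 3 planted factors at effect scale 3.5 and
unit noise.

## Known limitations

* The generator's band independence understates the covariance structure
  of real serum spectra; classification on synthetic cohorts is therefore
  easier than on real data at matched effect sizes.
* The Lorentzian tail field in crowded regions places a floor (~2 counts)
  under any polynomial baseline estimate; apex recovery is accurate to a
  few percent, not exact.
* Welch's ANOVA and the other comparisons treat bands independently; no
  band-to-band correlation model is used.
* ROC curves for the three-class task are one-vs-rest for a single
  designated class, not micro-averaged.
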
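# Methods

## The model

`autologit` analyses a binary outcome Y_i (in-hospital death) observed at
projected planar locations (x_i, y_i), with patient-level covariates X_i.
The auto-logistic model augments the logistic linear predictor with one
spatial term:

    Y_i ~ Binomial(p_i)
    logit(p_i) = β'X_i + γ · autocov_i,
    autocov_i  = Σ_j w_ij y_j / Σ_j w_ij,   w_ij = 1/d_ij  for 0 < d_ij ≤ r.

The autocovariate is the inverse-distance-weighted mean of neighbour
outcomes inside a distance band of radius r, a convex combination of 0/1
values and hence in [0, 1].  γ > 0 means a patient's odds of death rise
with the observed mortality of nearby patients — shared neighbourhood risk
that the measured covariates do not explain.

**Estimation.** The observed outcomes are plugged into the autocovariate
and the resulting ordinary logistic likelihood is maximised.  This is
maximum pseudolikelihood for the autologistic Markov random field.  It is
simple and consistent in the sparse-interaction regime used here, but the
autocovariate is built from the outcome itself, so the reported standard
error for γ is pseudolikelihood-based and approximate; the model card flags
this.  β inference is standard and is verified by simulation (coverage
checks below).  No correction (Firth, sandwich, block bootstrap) is
applied, matching common applied practice for this model.

**Fitting.** Iteratively reweighted least squares (Fisher scoring) with
step-halving; convergence when max |score| < 1e-8 or the relative
log-likelihood change < 1e-10, capped at 50 iterations.  Rank deficiency is
detected up front by pivoted QR and reported with the offending column
names.  Complete separation leaves the score and likelihood looking
converged while coefficients drift to ±∞; it is detected from the
standardised coefficient magnitude (|β_j|·sd(X_j) > 15) and reported as
non-convergence naming the diverging term rather than silently returned.
Wald 95% CIs are computed on the log-odds scale and exponentiated to the
OR scale.  AIC = 2k − 2·logLik.

## Spatial machinery

**Weights.** Distance-band inverse-distance weights on projected metres.
The default band radius is the maximum nearest-neighbour distance (no unit
isolated), the common convention for irregular points; any fixed radius can
be given.  Coincident points make 1/d undefined and raise an error naming
the pair; a seeded ±0.5 m jitter utility is provided.  Longitude/latitude
input is projected with a local equirectangular projection (distance error
well under 0.5% at city scale, verified against a haversine oracle).

**Isolated units** (no neighbour within the band) keep their rows: their
autocovariate is the overall outcome prevalence — a constant that injects
no spatial signal — and they are flagged.  This keeps the design matrix
complete without inventing neighbours.

**Moran's I.** Global I uses the cross-product form with row-standardised
weights by default (raw inverse-distance available).  Inference is by
random relabelling: 999 seeded permutations, pseudo p
= (1 + #extreme) / (1 + n_perm).  `global_morans_i` is two-sided around
E[I] = −1/(n−1) by default, with `greater`/`less` alternatives.  Local
Moran (LISA) uses conditional permutation — unit i's value is held and the
others are resampled onto its neighbour slots — and classifies significant
units as HH/LL/HL/LH from the signs of the centred value and its lag.  The
implementation satisfies Σ_i I_i = S0 · I_global exactly and matches a
brute-force double-sum oracle on every small instance tested.

**Residual diagnostic.** After each fit, residuals are tested with the
Moran permutation test.  Two defaults differ deliberately from the obvious
choices, for reasons visible in simulation:

- *Deviance residuals* (not Pearson): at ~14% prevalence Pearson residuals
  are extremely skewed and their cross-products make the diagnostic
  erratic, including over-flagging the correctly specified auto-logistic
  model.  Raw and Pearson remain available.
- *One-sided (`greater`) pseudo p*: the workflow's question is whether
  **positive** spatial autocorrelation remains after adding the
  autocovariate.  Moreover the pseudolikelihood fit conditions each unit on
  its observed neighbours, which mechanically induces slight *negative*
  residual correlation; a two-sided test rejects the correct model for this
  artefact.  The directional pseudo p is also what GeoDa-style software
  reports.  Under the null the permutation test retains its exact 5% level
  either way (verified: type-I ≈ 0.04 over 200 null replicates).

## Synthetic cohort generator

The registry behind the motivating analysis is private, so the package
ships a generator whose defaults emulate that cohort and whose provenance
record is the ground truth for recovery tests.

**Layout.** Eight residential clusters, each uniform in an 800 m-radius
disc, with cluster centres uniform in an 8 km city disc and the referral
hospital at the origin; `distance_to_hospital` is derived from the
geometry (implied distribution ≈ 5.9 ± 2 km, matching the published
5.9 ± 2.9).  A homogeneous uniform-disc layout is available.

**Covariates** are drawn independently per patient from published marginal
summaries: age ~ N(70.0, 13.8²) truncated at 18; 50.1% male; 67.5%
hypertensive; 84.1% urban; 69.1% triage levels 1–2; 25.5% final stroke
diagnosis; ambulance accessibility ~ N(27.3, 6.7²)⁺ per million; delay
~ N(37.3, 29.7²)⁺ s; response ~ N(9.0, 3.9²)⁺ and transport
~ N(21.5, 11.9²)⁺ min with revealed access their sum; screening
~ N(0.25, 0.3²)⁺ h; LOS ~ round(Lognormal(ln 3, 1.307)) days, whose median
(3), IQR (≈6) and P(LOS > 7) ≈ 0.23 match the published summaries.  Real
covariates are correlated (age–hypertension, accessibility–geography);
independence is a deliberate simplification because no joint distribution
is published, and it is one reason synthetic AUCs (~0.70) sit below the
published one.

**Outcomes** are drawn from the autologistic model itself by a
systematic-scan Gibbs sampler on the full conditionals
logit P(y_i = 1 | y_−i) = β'x_i + γ·autocov_i(y_−i), initialised from
independent Bernoulli(expit(β'x_i)) draws; the state after 200 sweeps is
returned (longer chains change nothing measurably; the row-normalised
coupling is asymmetric, so this is a pseudo-Gibbs process whose long-run
state approximately satisfies the stated conditionals).  All randomness
comes from the config seed; identical configs give byte-identical CSVs.

**Coefficients.** Default β mirrors the published adjusted effect sizes
(age 0.02/yr, triage 3&4 0.74, final diagnosis 0.47, accessibility −0.03,
screening −1.2/h, LOS 0.02/day, male 0.05, delay 0.003/s) with γ = 1.  The
intercept (−2.87) was calibrated by simulation so marginal mortality is
≈ 0.14 (published 14.3%); measured mean prevalence across seeds is 0.146.

**Interaction scale.** The generator's default band is a fixed 80 m
street/block micro-neighbourhood (mean degree ≈ 1.5; ~23% of patients have
no other patient that close and are isolated).  This is an identifiability
choice made by power analysis, not an estimate of any real interaction
range: the information about γ scales with n·p(1−p)·Var(autocov), and
Var(autocov) is maximal when units have few neighbours (approaching
p(1−p) at degree 1).  With wide bands the autocovariate is nearly constant
and γ = 1 is undetectable at n ≈ 1200; with the 80 m band the closed loop
generator → pseudolikelihood recovers γ essentially unbiasedly
(γ̂ ≈ 0.9–1.0 ± 0.4, positive in ≥ 95–98% of replicates).

**What passing tests show — and don't.** The simulation verifies the
estimator against data generated from its own model family with
independent covariates and a single known interaction scale.  Real
registry data adds correlated covariates, geocoding error, an unknown and
probably multi-scale dependence structure, and model misspecification;
none of these are emulated, so test results certify the machinery, not
field performance.

## Monte-Carlo verification design

- **Recovery study** (100 cohorts, n = 1200, γ = 1): β bias is asserted
  below 10% relative for every well-identified term; for the near-null sex
  coefficient (|β| = 0.05, SE(β̂) ≈ 0.3) the 100-replicate Monte-Carlo SE
  of the mean exceeds 10% of |β|, so its bias is asserted against a
  Monte-Carlo-aware bound max(0.10|β|, 2.5·MC-SE) instead.  Wald 95%
  coverage is asserted pooled over term × replicate pairs (per-term
  coverage at 100 replicates has binomial SE ≈ 2.2%, too noisy for a tight
  per-term band); measured ≈ 0.93.
- **Diagnostic study** (same replicates): ordinary-logistic residuals
  reject in ≈ 0.72–0.80 of replicates — at the physical ceiling for this
  field strength: γ = 1 implies a pairwise odds ratio of e ≈ 2.7, i.e. a
  neighbour φ-correlation of ≈ 0.11 at 14% prevalence, which caps one-sided
  Moran power near 85% even for an ideal pair graph.  Auto-logistic
  residuals reject in ≈ 0%, and the auto-logistic model wins on AIC in
  ≈ 86–91% of replicates — the qualitative pattern of the motivating
  analysis.
- **Null calibration** (200 cohorts, γ = 0): a pure-noise covariate passes
  the P < 0.25 univariate screen in ≈ 22% of replicates (expected 25%), and
  the Moran permutation test's type-I error is ≈ 0.04 at α = 0.05.

Problem sizes (100/200 replicates, n = 1200, 999 permutations) were chosen
to keep Monte-Carlo error small relative to the asserted bands while the
whole verification runs in well under a minute on one CPU (the Gibbs
kernel is numba-compiled, with a pure-Python fallback that is
bit-identical because all uniforms are pre-drawn).

## Pipeline conventions and limitations

- Descriptives: mean ± SD with Student's t-test for continuous variables
  (median (IQR) presentation for LOS), n (%) per level with Pearson's
  chi-square (no continuity correction) for categoricals; percentages are
  computed on non-missing rows per variable and rounded to one decimal only
  at presentation.  Tests on empty strata are marked not applicable.  No
  multiple-testing correction is applied anywhere, by design.
- Screening: per-candidate univariate logistic fits; Wald p for single-df
  terms, likelihood-ratio p for multi-level categoricals; P < 0.25 to
  enter the multiple models; failing candidates are excluded with a
  warning.  `revealed_access` is not a default candidate because it is the
  exact sum of response and transport times.
- Missing data: rows lacking coordinates or the outcome are dropped at
  load; models are complete-case per fit with logged counts.  The
  auto-logistic fit requires weights built on exactly the modelled rows.
- Continuous covariates are not rescaled (ORs are per natural unit).
- Out-of-sample prediction from the auto-logistic model requires neighbour
  outcomes; `AutoLogistic.predict_proba` therefore takes an explicit
  autocovariate vector and defaults to in-sample values.
- LISA p-values use a shared-permutation conditional scheme; at very small
  n the discreteness of the pseudo p dominates.
- Only point (patient-level) analysis is implemented; areal/contiguity
  weights, kernel smoothing and exact/Bayesian autologistic fitting are out
  of scope.  Zone aggregation of the autocovariate (mean per user-supplied
  polygon) supports choropleth-style mapping.
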
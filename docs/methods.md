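# Methods

## The model

`retscreen` models progression of diabetic retinopathy through four
person-level states graded from screening photographs:

1. no retinopathy detected,
2. non-referable retinopathy in one eye,
3. non-referable retinopathy in both eyes,
4. referable retinopathy (screen-positive) — absorbing.

Movement between states is a continuous-time Markov chain that is
homogeneous in *operational time* u = t^α, where t is years since the
person's first screen and α is a Weibull shape shared by all transitions.
α < 1 means transitions concentrate early in follow-up.  Only six
instantaneous moves are permitted — 1→2, 2→1, 2→3, 2→4, 3→2, 3→4 — and each
intensity is log-linear in centred clinical covariates:

    log λ_ij = β0_ij + Σ_C β_ij^C (C − c̄_C),

with C ranging over age at diagnosis (years), disease duration (years),
HbA1c (mmol/mol), systolic BP (mmHg) and total cholesterol (mmol/l).
exp(β_ij^C) is the per-unit hazard ratio of covariate C on transition i→j.
The intensities form a generator Q with rows summing to zero (row 4 is
zero; the 1→3, 1→4 and 3→1 entries are structurally zero), and the interval
transition kernel is

    P(t1, t2) = expm(Q · (t2^α − t1^α)),

which reduces to expm(Q t^α) from baseline.  For t1 > 0 this is the unique
extension of the baseline form that keeps the process Markov and
homogeneous in u; operational time accumulates from the subject's baseline
screen (a per-interval reset is available via the simulator's exact-path
machinery but is not the fitted model).

## Likelihood

Screening data are panel data: the state is seen only at visits, so
transition times are interval-censored.  Each consecutive pair of episodes
contributes log P_{s1,s2}(t1, t2), with Q rebuilt from the covariates
recorded at the interval's left endpoint (piecewise-constant convention).
Disease duration is by default carried at its first-episode value, since it
is assigned at the first screen; a flag switches to per-episode updating.
Arrival in state 4 is treated as interval-censored like any other
transition — screen-positive disease is *detected* at a screen, not timed.
Subjects are independent; the likelihood is the product over subjects.

## Estimation

`RetinopathyMarkovModel.fit()` maximises the panel likelihood with
L-BFGS-B.  Key numerical choices:

* **Parameterisation.**  Intercepts on the log-intensity scale (bounds
  −20 to 6); covariate coefficients internally standardised (per-SD scale,
  bounds ±5 per SD) for conditioning and reported per-unit; α estimated on
  the log scale in (0.05, 2].  Intensities are floored at 1e−12 and the
  linear predictor capped at 8 (≈3000/yr) to keep line-search excursions
  finite.
* **Gradients.**  Analytic.  Each interval matrix A = Q·Δu is
  diagonalised; the Fréchet derivative of expm in direction E is
  V (F ∘ V⁻¹EV) V⁻¹ with F the divided-difference matrix of exp over the
  eigenvalues, contracted against the one observed entry per interval.  The
  α-score uses the collapse of that formula to diag(w e^w) for directions
  proportional to A.  Near-defective interval matrices (detected when the
  eigen-reconstruction of P disagrees with the Padé value beyond 1e−9) fall
  back to central differences for that interval only.
* **Matrix exponentials.**  A vectorised scaling-and-squaring Padé-7
  routine for stacks of 4×4 generators (agrees with `scipy.linalg.expm` to
  ~1e−13); probabilities are clipped to [0, 1] only after verifying the
  overshoot is below 1e−9.
* **Convergence.**  ftol 1e−10 (relative), gradient tolerance 1e−6, max 500
  iterations; non-convergence raises an error carrying the best-so-far
  parameters unless the caller opts into warnings.
* **Uncertainty.**  Observed information by central differences of the
  analytic score at the optimum; covariance is its inverse (pseudo-inverse
  with a flag when singular).  Wald tests for a covariate are joint
  chi-square over its six transition coefficients.
* **Identifiability guard.**  A transition with no observed exposure from
  its source state has its intercept pinned at −20 and excluded from the
  free-parameter count.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) uses the number of *subjects* as n —
subjects are the independent units; episode counts would overstate the
information.  Covariate selection ranks candidates by their joint Wald
statistic in the full model (marginal ranking available), builds nested
models in rank order from the state-only baseline, and selects the smallest
AICc.  "% explained likelihood" is implemented as
100·(ℓ_k − ℓ_base)/(ℓ_full − ℓ_base); this is a documented interpretation of
a quantity whose exact definition is not fixed by convention.

## Missing data

Fitting uses multiple imputation by chained equations: iterated Bayesian
linear regressions over the five covariates conditioned also on observed
state and time, five burn-in cycles, posterior-predictive draws, m = 10
copies by default, each with an independent seeded stream.  Covariates
below 80% completeness are rejected rather than imputed.  Fits across
copies are pooled by Rubin's rules; predicted risks are pooled by averaging
probabilities (the decision quantity), not coefficients.

Deployed prediction instead uses a deliberate worst-case single imputation:
missing covariates are replaced by the 75th percentile (linear-interpolation
convention) of observed baseline values, biasing predicted risk upward.
The percentiles are stored inside the model file so deployed predictions
are self-contained.

## Risk prediction and interval allocation

For a person currently in state s ∈ {1,2,3}, the risk at horizon h is entry
(s, 4) of expm(Q h^α): the clock restarts at the prediction episode, since
the engine is rerun at every screen with fresh covariates.  The allocation
rule takes the longest candidate interval (6, 12, 24 months) whose risk
does not exceed the threshold (2.5% default; ties inclusive), falling back
to 6 months when even the shortest exceeds it.  Lowering the threshold can
only shorten intervals — this monotonicity is asserted in tests.

## Evaluation

Screen-positive event times are taken as the midpoint of the
last-negative-to-first-positive screening interval (exact simulated times
can substitute via the hidden-truth table).  Policy accounting over two
years multiplies the people allocated 6/12/24 months by 4/2/1 episodes and
compares with two episodes per person under an annual programme.  A
positive allocation is correct when the event time is at or after the
allocated screen; a negative is correct only when given the maximal
interval (so a fixed annual policy scores 0% correct on negatives by
construction), and negatives with under two years of follow-up are
excluded.

Discrimination: Harrell's C over comparable pairs (ties half) and
fixed-horizon AUC (event by h versus event-free through h; censored before
h excluded), with sensitivity/specificity from classifying risk strictly
above the threshold.  Internal validation is subject-level fourfold
cross-validation, stratified by baseline state to stabilise event counts
per fold, with held-out predictions pooled before scoring; bootstrap
optimism (B = 200 default, subject-level resampling) estimates the
apparent-minus-true gap for any metric and is subtracted to correct it.

## The synthetic-data generator

`simulate_cohort` draws exactly from the model class the likelihood
assumes, so it doubles as a generative oracle:

* covariates per subject at baseline, independent truncated normals with
  means/SDs/floors plausible for a UK diabetes screening population —
  age at diagnosis N(55, 12²), duration N(10, 8²) (≥0), HbA1c N(58, 14²),
  SBP N(135, 15²), cholesterol N(4.8, 1.0²); an optional correlation matrix
  can couple them.  No claim is made of matching any particular cohort;
* baseline states drawn screen-negative with probabilities (0.65, 0.20,
  0.15) over states 1–3;
* exact event-driven simulation in operational time — competing exponential
  clocks in u, event times mapped back through t = u^{1/α} — rather than
  discretised stepping, so the hidden truth is exact;
* visits at gaps N(1.0, 0.15²) years, floored at 0.25, five visits by
  default (≈4 years of follow-up), states recorded only at visits, records
  truncated after the first observed state 4;
* missing-completely-at-random covariate masking up to the 20% the
  completeness rule allows (default 0 for fitting studies, 5% in the CLI
  example).

The reference generative model uses the reference per-unit hazard ratios
for all five covariates and baseline intensities calibrated so expm(Q)
reproduces the reference one-year baseline transition probabilities
(0.114, 0.552, 0.141, 0.0163, 0.283, 0.0574) — the calibration initialises
from the matrix logarithm of a completed one-year matrix projected to the
permitted zero pattern and refines by least squares, achieving residuals at
machine precision (tolerance 1e−3).  α = 0.9.

Because covariates are fixed at baseline and visits are non-informative,
passing tests show correctness of the *method* under its own assumptions;
they say nothing about time-varying risk factors, informative scheduling,
grading misclassification or eye-level disease, none of which the generator
emulates.

## Study sizes used by the replication studies

Chosen as stable, single-CPU-friendly designs:

* parameter recovery: 10 replicates of n = 2000 subjects, five annual
  visits, α estimated.  Recovery quality is summarised by the *pooled*
  median absolute hazard-ratio error (<0.01) and pooled 95%-CI coverage
  (≥90%) across all 30 coefficients × replicates.  Pooling is deliberate:
  information for a per-unit cholesterol effect on the rare 2→4 transition
  is bounded by its ~30–40 events per cohort (sampling SE ≥ 0.04 for any
  estimator), so per-coefficient precision targets are unattainable for the
  rare transitions at this design size while the common transitions carry
  the pooled summary;
* Monte-Carlo generative check: 50,000 subjects per start state observed at
  exactly one year against expm(Q) (worst-case MC SE ≈ 0.002);
* cross-validation: n = 5000 so the 2-year horizon (~2.5% cumulative
  incidence) yields ≈125 classifiable events, keeping the AUC's MC SE near
  0.02;
* policy studies: n = 1000 with allocation at baseline.

## Known limitations

* One shared α; the likelihood cannot express transition-specific shapes.
* No misclassification (hidden-Markov) layer: observed states are taken as
  true states.
* Covariates are piecewise-constant between screens; within-interval drift
  is invisible to the likelihood.
* The C-index for interval-censored events uses midpoint times; with short
  panels this coarsens the risk ordering.
* The chained-equations imputer assumes approximately linear relations
  among covariates and ignores the future state path.
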
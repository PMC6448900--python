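# retscreen

Risk-based screening intervals for diabetic retinopathy.

Population screening programmes photograph the eyes of people with diabetes
at fixed (usually annual) intervals to catch referable, sight-threatening
retinopathy early.  A fixed interval over-screens the many people at low
risk and under-screens the few at high risk.  `retscreen` implements the
statistical engine behind individualised, variable-interval screening: it
fits a progression model to routinely collected screening panel data,
predicts each person's probability of becoming screen-positive by 6, 12 and
24 months, and allocates the longest interval whose risk stays within an
accepted threshold (2.5% by default).  It is aimed at biostatisticians and
screening-programme analysts.

## The model

Retinopathy is modelled as a four-state continuous-time Markov chain —
(1) no retinopathy, (2) non-referable in one eye, (3) non-referable in both
eyes, (4) referable / screen-positive (absorbing) — homogeneous in Weibull
*operational time* u = t^α.  Each of the six permitted transition
intensities is log-linear in centred clinical covariates,

    log λ_ij = β0_ij + β_ij^AgeD·AgeD + β_ij^DiseaseD·DiseaseD
             + β_ij^HbA1c·HbA1c + β_ij^Chol·Chol + β_ij^SBP·SBP ,

assembled into a generator Q (rows sum to zero), and the probability of
moving between states over a screening interval is the matrix exponential

    P(t1, t2) = exp( Q · (t2^α − t1^α) ),      P(t) = exp(Q t^α) from baseline.

α < 1 makes transitions more likely early.  Because states are seen only at
screening visits, transition times are interval-censored; the likelihood of
a subject's visit sequence is the product of the observed entries of the
interval kernels, which the package maximises with analytic gradients.
Around the core model sit the supporting machinery of a deployable engine:
Wald/AICc nested covariate selection, chained-equations multiple imputation
(worst-case 75th-percentile imputation at prediction time), k-fold
cross-validation, bootstrap optimism correction, C-index and fixed-horizon
AUC, screening-policy episode accounting, and an exact event-driven cohort
simulator for end-to-end validation without any patient data.

## Worked example

```python
from retscreen import (SimulationConfig, simulate_cohort,
                       RetinopathyMarkovModel, predict_subject)

panel, truth = simulate_cohort(SimulationConfig(n_subjects=1000, seed=11))
results = RetinopathyMarkovModel(
    panel, covariates=("disease_duration", "hba1c")
).fit()
print(results.summary())
```

```
Retinopathy progression model (Weibull operational-time Markov)
========================================================================
subjects: 1000   episodes: 4927   intervals: 3927
log-likelihood: -2536.136   AICc: 5111.047   free parameters: 19
converged: yes (36 iterations, |grad|_max 1.82e-03)
Weibull shape alpha: 0.9444 (95% CI 0.8642, 1.0322)

Baseline 1-year transition intensities exp(beta0):
  1->2: 0.23355
  2->1: 1.04195
  ...
Per-unit hazard ratios exp(beta) (95% CI):
  disease_duration:
    1->2: 1.0346 (1.0187, 1.0508)
    ...
```

The intercepts are baseline intensities per year of operational time; the
hazard ratios are multiplicative effects per covariate unit (here, each
extra year of diabetes duration raises the 1→2 intensity by ≈3.5% in this
simulated cohort, whose generating value is 2.8%).  The fitted shape
α ≈ 0.94 (CI covering the generating 0.9) says transitions concentrate
slightly early.  Prediction and allocation for a new person:

```python
model = results.transition_model()
pred = predict_subject(model, "new-patient", state=2,
                       covariates={"disease_duration": 18.0, "hba1c": 75.0})
print(pred.risks)               # {0.5: 0.0195, 1.0: 0.0372, 2.0: 0.0694}
print(pred.interval_months)     # 6
```

With long-duration, poorly controlled diabetes and existing one-eye
disease, the 6-month screen-positive risk (1.95%) is the only one under the
2.5% threshold, so the engine recalls this person at 6 months; a baseline
person in state 1 gets 24 months.

The same workflow is scriptable from a shell:

```bash
retscreen simulate --n 1000 --seed 11 --out panel.csv --truth-out truth.csv
retscreen fit panel.csv --out model.txt
retscreen predict model.txt panel.csv --out predictions.csv
retscreen validate panel.csv --folds 4
retscreen evaluate-policy predictions.csv panel.csv
```

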
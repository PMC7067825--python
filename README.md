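# physdys

Composite physiological-dysregulation scoring and mortality analysis for
two-generation family cohorts.

Biological aging shows up as coordinated drift of many routine biomarkers
away from the "normal" physiological state, even while each individual
marker stays inside its clinical range. `physdys` implements the
statistical-distance approach to measuring that drift and relating it to
mortality: it is aimed at biodemographers and biostatisticians working
with family-based aging cohorts (baseline biomarker panel, health-deficit
questionnaire, long mortality follow-up, related subjects).

The score at the core of the package is the Mahalanobis distance

    D_M(x) = sqrt((x − μ_s)ᵀ Σ_s⁻¹ (x − μ_s))

of a subject's Box-Cox-transformed, standardised biomarker vector `x`
from the centroid `μ_s` of a sex-matched reference population (baseline
age < 60 by default), scaled by the reference covariance `Σ_s`. Around it
the package provides:

- **`physdys.cohort`** — a synthetic two-generation family-cohort
  generator (biomarkers with known age correlations and family ICC,
  deficit items, Gompertz mortality driven by a latent dysregulation
  score) so every stage is testable by parameter recovery;
- **`physdys.preprocess`** — Box-Cox + standardisation with the 0.1
  zero-shift rule, serialisable transform specs;
- **`physdys.dysregulation`** — reference-model fitting (sex- and
  optionally country-stratified, healthy-only / spouse-excluded
  variants), the score itself, its Box-Cox transform, quartiles, and
  biomarker-subset sensitivity rules;
- **`physdys.deficits`** — an 85-item-style deficits (frailty) index with
  the number-measured denominator and the <20%-missing eligibility rule;
- **`physdys.survival`** — left-truncated Cox models on the age scale
  with family-clustered sandwich variance, HR-per-SD reporting, quartile
  models, a proportional-hazards test and conditional Kaplan–Meier
  curves with hazard-based confidence bands;
- **`physdys.prediction`** — leave-one-out cross-validated logistic
  models, ROC/AUC, and paired DeLong (or family-bootstrap) tests of AUC
  differences between the four nested model variants
  (none / DI / D_M / D_M+DI);
- **`physdys.imputation`** — fully conditional multiple imputation with
  per-dataset score recomputation and Rubin's-rules pooling.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import physdys as pk

# a ~3,300-subject synthetic family cohort with a true mortality effect
# of HR 1.4 per SD of latent dysregulation
table = pk.generate_cohort(pk.CohortSpec(seed=1))

# Box-Cox, sex-stratified reference (<60y), Mahalanobis score, DI
scored, ref_model, transforms = pk.score_cohort(table)

# left-truncated, family-clustered Cox model of mortality
fit = pk.run_cox_analysis(scored, terms=("dm", "di"))
hr, lo, hi = fit.hr_per_sd
print(f"HR per SD of D_M: {hr:.2f} [{lo:.2f}, {hi:.2f}]  "
      f"(n={fit.n}, deaths={fit.n_events})")

# LOOCV ROC/AUC comparison of the four nested prediction models
res = pk.run_auc_analysis(scored)
print({k: round(v, 3) for k, v in res["auc"].items()})
c = res["comparisons"]["dm_di"]
print(f"dAUC(dm_di vs none) = {c.dauc:.4f}, p = {c.p:.2e}")
```

prints (seed 1):

```
HR per SD of D_M: 1.18 [1.10, 1.26]  (n=3308, deaths=1494)
{'none': 0.89, 'di': 0.896, 'dm': 0.897, 'dm_di': 0.898}
dAUC(dm_di vs none) = 0.0078, p = 5.48e-06
```

Reading the output: the measured score carries an independent mortality
signal even after adjusting for the deficits index, age (the time scale)
and the other covariates — the hazard ratio per SD is well above 1 with a
CI excluding 1 — and adding the composite measures to the covariate-only
logistic model significantly improves out-of-sample discrimination of
follow-up death. The HR is attenuated relative to the generating HR of
1.4 because the measured score is a noisy proxy of the latent one and the
model also adjusts for the DI, which shares that latent signal (drop the
`di` term for the cleaner recovery comparison).

The same pipeline is scriptable from the shell:

```sh
physdys simulate --seed 1 --out cohort.csv
physdys score --in cohort.csv --out scored.csv --ref-cutoff 60
physdys cox --in scored.csv --terms dm,di
physdys km --in scored.csv --condition-age 80 --out km.csv
physdys auc --in scored.csv
physdys impute --in cohort_with_missing.csv --m 25 --analysis cox
```

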
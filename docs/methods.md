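# Methods

## The dysregulation score

`physdys` quantifies a subject's physiological dysregulation as the
Mahalanobis statistical distance of their biomarker profile from the
centre of a younger reference population:

    D_M(x) = sqrt( (x − μ)ᵀ Σ⁻¹ (x − μ) )

where `x` is the subject's vector of Box-Cox-transformed, standardised
biomarkers, and `μ`, `Σ` are the mean vector and covariance matrix of the
same transformed biomarkers in the *reference population*. The distance
convention (square root of the quadratic form) is used rather than the
squared form; the two are monotone-equivalent for ranks and quartiles, but
not for hazard ratios per SD, so the choice is fixed and recorded in the
score provenance.

Key conventions:

* **Transformation.** Every biomarker is Box-Cox transformed and
  standardised to zero mean / unit variance before entering the score.
  The exponent λ is chosen by profile maximum likelihood over a grid on
  [−3, 3] with step 0.01, with exact ties broken toward λ = 1; the grid is
  evaluated in closed vectorised form and matches
  `scipy.stats.boxcox_llf` to 1e-10. Variables whose minimum is ≤ 0 are
  first shifted by a fixed offset of 0.1 (zeros arise naturally in
  panels with detection floors; the generator reproduces them by flooring
  Gaussian draws at zero). λ, the centre and the scale are fitted on all
  complete-case subjects with sexes pooled; only the reference moments
  below are sex-specific. Fitting λ on the full sample rather than the
  reference subsample is a deliberate choice where the procedure was
  genuinely open — it uses all the information about each marginal shape
  and leaves the reference definition to the moment stage.
* **Reference population.** By default all complete-case subjects with
  baseline age strictly below 60 years. μ and Σ are computed separately
  for females and males (sample covariance, n−1 denominator), optionally
  further stratified by country group (Denmark vs US field centers), and
  optionally restricted to disease-free subjects (no prevalent cancer,
  CVD, diabetes, AD/dementia) and/or non-spouses. Reference subjects are
  themselves scored against their own model.
* **Inversion.** Σ is Cholesky-factorised; a non-positive-definite
  covariance is an error that names the most collinear biomarker pair —
  no silent ridge regularisation, since the decorrelation sensitivity
  analysis exists precisely to deal with collinearity. The condition
  number is recorded in the model.
* **Score transform.** `D_M` itself is Box-Cox transformed and
  standardised (pooled over all scored subjects, sexes together — a
  second open choice, made for the same reason as λ above); a raw mode
  passes the untransformed distance through for sensitivity analysis.
* **Quartiles.** Cut points are the 25/50/75th percentiles (linear
  interpolation between order statistics) of the defining sample —
  optionally per sex and/or restricted to subjects under observation past
  a conditioning age; intervals are half-open `(low, high]` with ties to
  the lower bin.
* **Panel subsets.** Sensitivity variants keep biomarkers by
  |corr with age| thresholds (0.05–0.2), by the sign of the age
  correlation, or drop one member of every pair with |pairwise r| > 0.8
  (the member with the larger mean absolute correlation to the rest; ties
  keep the earlier marker in panel order). Correlations are Pearson on
  the transformed scale.

## The deficits index

The DI is the sum of a subject's deficit scores (dichotomous items coded
0/1, ordinal items recoded to fractions of 1 via config tables) divided by
the number of items *measured* in that subject, hence always in [0, 1]
and tolerant of item-level missingness. The default synthetic item set has
85 items; the module is item-agnostic. A sensitivity rule declares the DI
missing when ≥ 20% of items are unmeasured (subjects with strictly less
than 20% missing are retained). The main analysis imposes no cap.

## Survival analysis

Age is the time scale; a subject enters the risk set at baseline age
(left truncation / delayed entry) and exits at death or censoring. Rows
with zero follow-up (exit equal to entry — subjects lost immediately
after baseline) are dropped before fitting with a logged count.

* **Estimation.** Cox partial likelihood with Efron tie handling via
  `lifelines`; covariates are sex, field center (three dummies, Denmark
  reference), education, smoking, three medication flags and fasting,
  plus the score(s) under study.
* **Cluster-robust variance.** Families are the cluster unit. The
  sandwich variance is computed in-package from Breslow-form score
  residuals accumulated on the left-truncated risk sets, grouped by
  family: `I⁻¹ (Σ_g U_g U_gᵀ) I⁻¹`. (The delegated fitter's own robust
  option does not propagate delayed entry into its residuals and
  overstates the SE; our implementation agrees with
  `survival::coxph(..., cluster(id))` in R to ~1e-8 relative.)
* **Effect scale.** Hazard ratios for the score are reported per standard
  deviation of the transformed score in the analysed stratum:
  `exp(β·sd)`, CI `exp((β ± 1.96·robust SE)·sd)`.
* **Quartile model.** Q2–Q4 indicators against Q1; each quartile must
  contain at least one event.
* **Proportional hazards.** Grambsch–Therneau scaled-Schoenfeld score
  test against the identity transform of age, computed on delayed-entry
  risk sets with per-event Breslow weighting; calibration (null
  uniformity) and power (sign-flipping effect) are verified by
  simulation in the test suite.
* **Conditional Kaplan–Meier.** Product-limit estimate with risk sets
  entering at `max(entry age, conditioning age)` (default 80 years). The
  95% band is built on the Nelson–Aalen cumulative hazard:
  `exp(−exp(log Ĥ ± 1.96·SE(log Ĥ)))` with the Poisson-type variance
  `Σ d/n²`, which keeps bounds inside [0, 1]; bounds are additionally
  clipped to bracket the point estimate (relevant only at a terminal
  step where the product-limit estimate reaches 0 while Ĥ is finite).

## Prediction comparison

Four nested logistic models for death during follow-up — base covariates
plus baseline age ("none"), plus DI, plus D_M, plus both — are compared
by ROC/AUC on *leave-one-out* scores: subject i's probability always
comes from a model fitted without subject i, in deterministic row order.
The logistic fits are exact unpenalised MLEs from a Newton solver
warm-started at the full-data solution (verified against statsmodels to
1e-7); warm starting makes n refits cost a few full fits.

AUC is the Mann–Whitney concordance probability (ties at 1/2). dAUC
inference uses the paired DeLong asymptotic test on the per-subject score
pairs (verified against R pROC to 1e-7); a cluster-aware variant keeps
the same point estimate and takes the variance from a seeded bootstrap
over whole families (default 2000 resamples). Because the score pairs
come from LOOCV rather than in-sample fits, p-values are not expected to
reproduce any particular in-sample analysis numerically.

A caveat worth knowing: exact LOOCV induces a small *pessimistic*
artifact under weak signal — removing a subject's own outcome shifts
their held-out probability against their class. With informative
covariates (AUC ≳ 0.7) the artifact is negligible; in pure-noise designs
it biases the cross-validated AUC below 0.5 and inflates its spread
(measured SD ≈ 0.035–0.042 at n = 500 across 2–15 covariates, versus
≈ 0.028 intrinsic sampling noise), so null-calibration checks of LOOCV
AUC need wider bands than the intrinsic binomial argument suggests.

## Multiple imputation

Missing biomarkers (on the transformed scale) and binary covariates are
imputed by fully conditional specification: each incomplete variable is
regressed on the others plus always-complete predictors (baseline age,
sex), sweeping in fixed order (default 10 sweeps per chain, m = 25
chains with seeds derived from one master seed). Draws are proper —
linear models draw σ² from its scaled inverse-χ² posterior and β from
N(β̂, σ²(XᵀX)⁻¹) before adding residual noise; logistic models perturb β̂
by its asymptotic covariance before Bernoulli draws — so Rubin's rules
apply. Observed values are never altered. The pipeline order inside each
completed dataset is fixed: impute → fit reference moments → compute and
transform D_M → analyse (Cox or dAUC); pooling uses Rubin's rules (total
variance = within + (1 + 1/m)·between, small-sample df, t reference).
Only the joint biomarkers-plus-covariates scenario is implemented; the
biomarkers-only variant is a strict special case of the same machinery.

## The synthetic cohort generator

The generator emulates a two-generation family study: per family,
probands-and-siblings (default 3), their spouses (probability 0.3 each),
offspring (Poisson, mean 1.6 per proband) and offspring spouses. Baseline
ages are truncated normals per stratum (probands 90.4 ± 6.4 on [49, 110],
their spouses 83.4 ± 7.0, offspring 60.5 ± 8.3 on [30, 88], offspring
spouses 60.9 ± 8.7), giving an overall ~24–110 year range and a ~40%
under-60 reference fraction. The default 19-biomarker panel reproduces
the marginal means, SDs and age correlations of a real inflammation /
hematological / metabolic / endocrine / renal panel; each biomarker is
Gaussian linear in standardised age with a per-family random intercept
(default ICC 0.15) and independent residuals across biomarkers, with
heavily right-skewed analytes floored at zero to create genuine zeros.
Covariate and prevalent-disease frequencies are generation-specific and
match a field study of this design; per-variable MCAR missingness rates
mirroring such a study ship as `DEFAULT_MISSING_RATES` but are off by
default.

The latent dysregulation score `true_dm` is the standardised Euclidean
norm of the standardised age-adjusted biomarker residual vector — a
Mahalanobis-type deviation from the age expectation under the generator's
diagonal residual covariance. Mortality is Gompertz
(`a·exp(b·age)`, defaults a = 2e-5, b = 0.097 — hazard ≈ 0.007 at 60 and
≈ 0.13 at 90) multiplied by `exp(log(1.4)·true_dm)` by default; death
ages are drawn exactly by inverse transform conditional on being alive at
baseline, and censoring is administrative at baseline + 12 years. A small
fraction (0.6%) of subjects is marked lost-to-follow-up immediately after
baseline to exercise the zero-follow-up drop rule. Deficit items are
Bernoulli with logits linear in age (slope 0.05/yr) and in `true_dm`
(slope 0.5), with heterogeneous per-item intercepts N(−2.2, 0.8).

What the generator does *not* emulate: cross-biomarker residual
correlation (no joint correlation structure is published for the panel;
the identity choice makes the latent score well-defined but means
passing tests do not validate behaviour under strong biomarker
collinearity beyond the dedicated decorrelation tests), non-Gaussian
marginal shapes beyond the zero-floor, informative missingness, shared
spousal environment, and recruitment-driven selection of exceptionally
long-lived families. Parameter-recovery results on this cohort therefore
validate the machinery, not any real-data effect size.

### Parameter recovery and attenuation

The measured, transformed score is an error-prone proxy of `true_dm`
(estimated reference moments, age-driven displacement, transform
nonlinearity), so the fitted log-HR per SD of measured D_M is attenuated
relative to log 1.4. The recovery tests use a regression-calibration
target: per replicate, `true_dm` is regressed on (measured score,
baseline age); with slope γ the target is `exp(γ·log 1.4·sd_dm)`.
Conditioning on age mirrors the Cox model's age time scale, under which
comparisons are made within age-matched risk sets. The 95% robust CI is
required to cover this target (±0.05) in ≥90% of replicates.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of ~3,000 subjects in 20-member
families (150 families) with 100 replicates for Cox recovery and null
calibration and 50 replicates for the AUC power and null checks — sizes
chosen so each check is decisive at a few minutes of compute. Tolerances:
exact oracles at 1e-8–1e-10; CLT-based checks at 3 SE; frozen
cross-implementation oracles (R `survival`, R `pROC`, statsmodels) at
1e-5–1e-7. Degenerate inputs (singular covariance, empty quartiles,
single-class folds, 100%-missing variables, zero follow-up) raise typed
errors rather than producing numbers.
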
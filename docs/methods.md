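# Methods

This package implements a treatment-response inference pipeline for ALS
cohorts compared against a historical-control pool: survival contrasts,
matched-pair bootstrap validation, functional-decline models, a
historical-control survival model that classifies treated patients by their
survival residual, and a multimodal biomarker signature that predicts that
classification early in treatment. Because the individual-level data such
analyses run on (a pooled clinical-trials database and a small treated
cohort) are access-restricted, the package ships a synthetic-cohort
generator that reproduces the statistical structure the analyses assume;
every stage is therefore exercisable, and testable against generator truth,
without any download.

## Synthetic cohorts

**Survival.** Patient covariates (age, sex, onset site, baseline ALSFRS-R,
treatment latency, riluzole use) are drawn at the descriptors of a
riluzole+placebo historical pool (age 58.4 y, ALSFRS-R 36.9/48, latency 557
days) and of a younger treated cohort (51.9 y, 37.6/48, 595 days). Survival
is exponential with hazard `h_i = h0 * exp(x_i . beta)`, covariates centered
at the spec means so `h0` is the hazard of the mean patient
(`h0 = ln 2 / 398 d`, a ~13-month median). Censoring is administrative at a
fixed horizon (default 4 years). A latent responder flag (probability 0.5,
optionally age-dependent) multiplies the event time by an event-time ratio
(default 2.5) before censoring. Internal time unit is days; months are
days/30.44.

**Trajectories.** ALSFRS-R visits follow
`score(m) = clip(baseline + slope*m + noise, floor, 48)` at monthly visits
strictly before death/censoring. Two features matter:

* *Slope-survival coupling.* The per-patient slope is tied to the patient's
  realized survival percentile through a Gaussian copula
  (`slope = mean + sd*(rho*z + sqrt(1-rho^2)*eps)`, default `rho = 0.9`,
  `sd = 0.8` points/month, slopes truncated at -0.05). Fast decliners die
  sooner — the defining link between progression rate and survival in ALS
  and the premise that makes a slope-based survival model individually
  predictive. The copula leaves both marginals untouched, so the closed-form
  exponential checks still hold exactly.
* *Delayed attenuation.* Responder decline is multiplied by the attenuation
  factor (default 0.5) only from an onset month (default 3): a treatment
  effect on progression needs an induction period, so the first-3-months
  slope still reflects pre-effect progression — which is what the responder
  model uses as its covariate.

**Biomarkers.** Three packages (DTI fractional anisotropy per ROI, cytokines,
hematology/stem-cell counts) follow a 2-factor model
`values = L (f + effect*flag) + noise` per timepoint, with the first factor
shifted by responder status (cytokines negatively: responders are less
inflammatory). Ordinal variables are quantile-binned (preserving
monotonicity, which is what the NLPCA's optimal scaling assumes); entries are
deleted completely at random; imaging is only available at month 12,
exercising the absent-package path. Latent flags are returned separately
from all tables and only the truth files and tests may join them.

## Survival engine

Kaplan-Meier (Greenwood/log-log 95% bands, median = earliest time with
S <= 0.5, flagged undefined otherwise), multi-group log-rank and
at-risk-weighted Wilcoxon tests, and Cox regression with Efron tie handling
are delegated to lifelines. The parametric exponential PH regression
(`hazard = exp(b0 + x.b)`, product interaction columns supported) is a
direct Newton maximum-likelihood fit — the log-likelihood is concave, so
convergence is global; covariates are standardized internally and reported
on original scales with Wald chi-square tests. The AFT model defaults to
Weibull (lifelines), reporting the event-time ratio `exp(coef)` per
covariate; an exponential option uses the exact ETR = 1/HR duality.

## Matched pairs

Each treated patient gets its k = 10 nearest controls by Mahalanobis
distance on standardized matching covariates (default age and baseline
ALSFRS-R), greedily without replacement in a seed-randomized treated order.
Match quality is validated by TOST equivalence (default margin 0.5 pooled
SD, alpha 0.05). The bootstrap draws 9 of each patient's 10 controls,
computes per-arm KM medians and the arm-difference p of the Yang-Prentice
short-/long-term hazard-ratio model

    HR(t) = th1*th2 / (th1*F0(t) + th2*S0(t)),

which moves from `th1` at t = 0 to `th2` as t -> infinity and nests
proportional hazards at th1 = th2. We profile the baseline with a Weibull
law and maximize the joint likelihood (Nelder-Mead, 4 parameters); the
arm-difference test is a 2-df likelihood ratio against the pooled Weibull
null, replaced by a label-permutation null when either arm has fewer than 30
subjects. Summaries follow the mean-of-medians convention with the median
and range of per-draw p values. The short/long split is weakly identified
at moderate n — single-sample estimates at 1,000/arm scatter by ~+-0.3
around the truth — hence recovery checks run at 5,000/arm.

## Functional decline

Per-patient slopes use the Theil-Sen estimator (median of all pairwise
score differences per month; ordinary least squares available), returning an
undefined-slope marker rather than raising when fewer than two distinct
visit times exist. The population model is a linear mixed model (REML,
statsmodels) of ALSFRS-R on group, a three-knot restricted cubic spline of
month (knots at the 10th/50th/90th percentiles of observed months, linear
beyond the boundary knots), the group-by-month interaction (difference in
steepness of decline), and adjustment covariates; random structure is a
per-patient intercept and slope with automatic, flagged fallback to
intercept-only and finally to OLS when the random-effects covariance is
singular (the zero-variance limit). The three-way variant adds
group-by-month-by-latency terms and evaluates the group contrast at a stated
latency (default 10 months). Analysis window defaults to the first 6
months.

## Responder model

An exponential GLM with reciprocal link, `mean survival = 1/(x.beta)` with
covariates ALSFRS-R slope, age, and treatment latency, is fitted by Newton
iteration (concave log-likelihood; step-halving preserves the positive
linear predictor; convergence at relative log-likelihood change < 1e-8) on
*deceased* controls only, requiring >= 10 training patients per coefficient.
Measured slopes are winsorized at -0.05 points/month before fitting and
scoring: noise-driven positive slopes otherwise cap the slope coefficient
through the positivity constraint of the reciprocal link. Predictions
`1/(x.beta)` are made for every patient (censored included); nonpositive
predictors are flagged per patient, never fatally.

Classification uses the signed residual observed - predicted with a
negligible-difference band (default +-60 days): responder above the band
(censored patients included — they have already outlived their prediction),
non-responder below it only when death was observed (a censored shortfall is
unprovable), non-assignable otherwise. The band width is configurable and
`sensitivity_sweep` tabulates label counts over a band grid; by construction
the non-assignable count is non-decreasing in the band. The waterfall table
sorts residuals descending with patient-id tie-breaks.

## Biomarker signature

Cytokine response is summarized per patient and variable as the signed
trapezoid area between the follow-up polyline and the baseline level
(concentration-months; missing intermediate points are bridged; the ramp
from month 0 to the first follow-up is included, with a flag to start at
month 3 instead). Group contrasts use rank-sum tests, reported with a
p < 0.1 flag.

NLPCA is optimal-scaling alternating least squares: scalars standardized;
ordinals replaced by monotone quantifications (isotonic regression of the
current rank-r reconstruction on category order, re-fitted each cycle);
missing entries start at variable means and are re-imputed from the
reconstruction each cycle; convergence at reconstruction-error change
< 1e-6 (max 500 cycles, best iterate flagged otherwise). Loadings are
variable-score correlations, scores are normalized to mean 0 / SD 1, VAF is
the mean squared loading, and each component is oriented so its
largest-|loading| variable loads positive. In the complete all-scalar limit
the procedure equals classical correlation PCA exactly (tested to
congruence > 0.999).

For each evaluation window (3, 6, 12 months) all panels measured up to the
window are stacked so later windows accumulate repeated measures; each PC
(after the |loading| > 0.5 reporting threshold, read strictly) is tested for
a responder-group difference with a linear mixed model across timepoints
(single-timepoint input degrades to the equal-variance t-test). PCs
significant at alpha = 0.05 feed the meta-PC: the first principal component
of the patient-by-significant-PC matrix of per-patient mean scores,
sign-oriented toward the responder group. Its ROC AUC uses the
midrank Mann-Whitney formulation with a seeded label-permutation p-value.
Packages absent at a window are skipped; zero significant PCs give an
explicit empty signature, not an error.

## Pipeline

`run_pipeline` executes simulate -> survive -> match -> decline -> respond
-> signature from a single YAML-mappable config; stage seeds derive from the
run seed so stages can be re-run in isolation; every artifact is CSV with
its SHA-256 in `manifest.json`, and identical config+seed reproduces
byte-identical hashes. Latent truth lands only in `truth_*` files that no
stage reads (a test greps all other artifacts for the quarantined column).

## What the generator does and does not emulate

It reproduces: right-censored exponential survival with covariate effects,
the progression-survival link, a latent responder subgroup with an
event-time multiplier and delayed decline attenuation, factor-structured
multimodal biomarkers with ordinals and missingness, and visit truncation at
death. It does not emulate: non-exponential baseline hazards (real ALS
hazards rise), informative censoring or dropout, visit-schedule
irregularity, covariate correlations (drawn independently), assay
batch/limit-of-detection effects, or any genetic structure. Passing tests
therefore demonstrate the *procedures* recover known structure under their
own assumptions, not that effect sizes transfer to real cohorts.

## Numerical choices and problem sizes

Tolerances: GLM 1e-8 relative log-likelihood; NLPCA 1e-6 reconstruction
error; Newton exponential PH 1e-10. Ties: Efron (Cox), midranks (AUC),
patient-id (waterfall). Degenerate inputs: undefined slopes and medians are
flagged, never raised, wherever patients must stay in downstream tables.
The test suite runs its simulation checks at sizes chosen for a single CPU:
KM closed form at n = 20,000; log-rank calibration over 1,000 nulls; GLM
coverage over 300 replications at n = 2,000; responder recovery over 50
seeds of the default 2,000+36 scenario; decline power over 200 seeds at
36+500 patients; signature recovery over 50 seeds at n = 36; YP recovery at
5,000/arm. The factor-recovery comparison uses Tucker congruence after
orthogonal Procrustes alignment to the generating loadings, the standard
rotation-invariant criterion.
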
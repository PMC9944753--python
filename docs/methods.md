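# Methods

`ehrcausal` estimates the marginal risk ratio (RR) between systolic
blood-pressure (SBP) exposure categories and a composite cardiovascular
outcome in a diabetic cohort, using cross-fitted nuisance models over coded
EHR histories and cross-validated targeted maximum likelihood estimation
(CV-TMLE), alongside the conventional estimators an epidemiologist would
fit to the same cohort. Because real UK primary/secondary-care data are
access-restricted, the package ships a synthetic cohort generator with
known counterfactual risks; every estimator is validated against that
ground truth or against independent brute-force oracles.

## The estimand and the study design

Patients enter at their first SBP measurement taken in 1990–2005 at age
50–90. SBP values outside [50, 300] mm Hg are discarded as gross
measurement errors. The exposure is the mean of the surviving SBP values
over the first 12 months after entry (the half-open day window
`[entry, entry+365)`), binned into six categories: <120 (reference),
120–129, 130–139, 140–149, 150–159, ≥160 mm Hg, with bins half-open on the
real line (`[120, 130)` etc.). Patients with heart failure before entry,
or with a composite cardiovascular event or dropout during the exposure
period, are excluded; exclusion reasons are assigned with the fixed
precedence prior-HF → event → dropout so the patient-flow accounting is
deterministic. The binary outcome is the first composite event (ischemic
heart disease, incident heart failure, stroke, or cardiovascular death) in
the follow-up window `(entry+365, entry+3650]` — months 12–120. A day is
the time unit throughout; a year is 365.25 days and "12 months" is 365
days, making every window boundary bit-exactly testable. An event on
exactly day `entry+365` belongs to the exposure period (the follow-up
window opens strictly after it).

Patients censored before the window closes (loss to follow-up or non-CV
death) keep outcome 0 with the censoring day recorded. This binary-outcome
treatment of censoring is a design limitation carried deliberately: the
Cox comparator exists precisely to check whether conclusions are an
artifact of it.

The estimand for category *a* is ψ_a/ψ_0, where ψ_a is the
population-standardized (g-computation) risk under assignment to category
*a*. Contrasts are pairwise — each category versus the reference — with
one nuisance model per contrast fitted on the two-category subset. A
multiclass propensity is deliberately out of scope of the default path.

## Synthetic cohort generator

One latent frailty U ~ N(0,1) per patient drives (i) emission of
designated comorbidity dx tokens in the pre-entry history, (ii) the
patient's latent mean SBP (shift `conf_strength * sbp_conf_slope * U`
mm Hg, or the one-sided `max(U,0)` variant in which only frail patients
have their SBP shifted — the reverse-causation mechanism), and (iii) the
outcome log-odds (`conf_strength * U`). Potential risks under all six
categories, `expit(β0 + β_a + βX·X + β_U·U)`, are stored on each record
before exposure is realized, so exchangeability holds by construction and
Monte-Carlo averages of stored risks are an exact oracle for ψ_a and the
true RRs. Exposure is realized from the latent SBP mean; the repeated
measurements add independent noise (default SD 10 mm Hg), so
adjacent-category misclassification arises naturally and is mitigated, as
in the study design, by 12-month averaging.

Default conditions (chosen to mirror the published cohort's population
statistics and held fixed): 6 exposure categories with a modest monotone
log-odds gradient (0, 0.03, 0.05, 0.08, 0.11, 0.17); baseline log-odds
−1.1 and a per-year dropout hazard of 0.040, which at desk scale reproduce
the reported ≈33% event and ≈26% censoring fractions over the nine-year
window; ~4 SBP measurements per year; overdispersed (gamma-Poisson)
pre-entry visit counts with median near 10 and a wide interquartile range,
matching routine primary-care contact patterns; covariate missingness of
20–25% for BMI and lipids, 10% for smoking and 45.1% for HbA1c. Dropout is
generated from observed covariates only (ignorable) unless
`frailty_dropout` is switched on to probe informative censoring. Baseline
covariates are generated as static values carried in `patients.csv`; the
12-month pre-entry averaging rule is therefore implemented for the
exposure only.

What the generator does **not** emulate: realistic clinical coding
vocabularies (the token set is synthetic: 60 dx + 20 rx codes),
practice-level clustering, calendar trends, diastolic BP, or genuinely
nonlinear covariate-outcome surfaces. Passing tests therefore demonstrate
estimator correctness and the confounding-recovery mechanism, not
transportability of any particular RR to real registries.

## Sequence model

A compact bidirectional transformer encoder over the pre-entry coded
history, implemented in numpy with analytic backward passes (verified
against finite differences in the test suite) and Adam. The input is a
CLS/sex/smoking header followed by dx/rx tokens grouped into day-level
visits separated by SEP; each token carries an integer age embedding
(0–119 years), a visit-parity segment embedding and a visit-order position
embedding. Sequences are truncated from the front (oldest events dropped)
to `max_len`. Calendar-year embeddings are omitted to keep the input set
minimal. Three heads share the encoder: a masked-code head over the
vocabulary (masked-EHR modeling: each code token is selected with
probability `mask_rate`=0.15 and replaced by MASK/random/kept with
80/10/10 splits), a propensity head for the non-reference arm, and two
arm-specific outcome heads, so risks under both arms are evaluable for
every patient — the form targeted learning needs. The joint loss is
`λ_mem·CE + λ_prop·BCE + λ_out·BCE(observed arm)` with all weights 1 by
default; an optional MEM-only pretraining phase is available
(`pretrain_epochs`), with co-training as the default. Desk-scale defaults:
2 layers, 4 heads, hidden 96, max_len 256, ≤10 epochs, early stopping on a
10% inner validation split by propensity+outcome loss.

Cross-fitting: folds are assigned by a seeded permutation stratified on
exposure category (per-category fold sizes differ by at most one —
stabilizes small categories); for each fold the model is trained on the
other folds and predicts the held-out fold, so no patient's nuisance
estimates come from a model that saw them. Held-out propensities are
truncated to [δ, 1−δ], δ = 0.01 by default, as positivity protection.

A cross-fitted logistic path with the same held-out contract
(`ehrcausal.nuisance`) serves the replicated calibration studies and any
setting where the nuisance functions are genuinely low-dimensional.

## Targeted estimation

Initial estimates (g, q1, q0) pooled across held-out folds are updated by
a one-parameter logistic fluctuation: ε maximizes the binomial likelihood
of Y under `expit(logit(q_obs) + ε·H_obs)` with clever covariate
`H_obs = A/g − (1−A)/(1−g)`, solved by Newton iterations to a mean score
below 1e−10. Per-arm predictions are updated with `H1 = 1/g`,
`H0 = −1/(1−g)`, standardized over the whole cohort to (ψ1, ψ0), and the
RR is the ratio of targeted marginal risks (targeting log-RR directly is
the noted alternative; the ratio of targeted means is used here). The 95%
CI comes from the efficient influence curve:
`Var(log RR) = Var(IC1/ψ1 − IC0/ψ0)/n`, normal quantile 1.96. Design
choices where the method description is open: a single shared ε (the
two-dimensional arm-specific fluctuation is not exposed), and pooled-fold
targeting (one ε on all held-out predictions) as the default CV variant —
chosen for small-sample stability — with per-fold targeting and averaged
risks available as an option. Forcing ε = 0 reduces the estimator exactly
to the g-computation plug-in of the initial fits, which is how the
doubly-robust comparisons isolate the targeting step's contribution.

## Conventional comparators

Crude RR with the textbook log-RR variance (reference rows are emitted
with RR 1 and no CI). Missing baseline covariates (BMI, HDL, total
cholesterol, triglycerides, smoking; plus HbA1c in the extended set) are
imputed by chained equations: Bayesian linear regression draws for
continuous variables, multinomial logistic sampling for smoking, outcome
and exposure included as predictors; m = 25 imputations, 10 cycles by
default. The adjusted logistic estimator fits outcome ~ exposure +
covariates on the training folds of the 5-fold split and standardizes
predicted risks over the held-out fold with exposure forced to each arm;
the point estimate is the mean of fold RRs averaged over imputations, and
the CI uses mean ± 1.96·SD(fold log-RRs)/√5 combined with
between-imputation variance by Rubin's rule (the fold-only CI is also
reported, since the convention is ambiguous). Logistic fits are
unpenalized IRLS (statsmodels GLM) so the algebraic identities hold
exactly — with no covariates the saturated MLE is the training group
means and the standardized RR equals the training-fold crude RR; a ridge
refit with a warning handles separation. The proportional-hazards check
is a lifelines Cox fit (Efron ties) on days since follow-up start, with a
scaled-Schoenfeld trend test and residuals exported for plotting.

## Validation studies and problem sizes

The packaged studies (`ehrcausal.studies`) are sized for a single desktop
CPU; each has an analytic or by-construction truth:

- **Coverage**: 50 replicates at n = 2000 of a one-confounder logistic
  law with the true RR computed by Gauss-Hermite quadrature; nominal 95%
  CIs should cover in roughly 42–50 of 50.
- **Null calibration**: 20 replicates with randomly assigned arm labels;
  the CI should contain 1 in ≥ 90%.
- **Double robustness**: correct propensity with an intercept-only
  (misspecified) outcome model at n = 5000; the targeted estimate's bias
  is compared with the untargeted plug-in of the same initial fit.
- **CI width scaling**: log-width vs log-n slope ≈ −1/2.
- **Spurious-J demonstration**: 20 replicates of a frailty-confounded
  cohort at n = 20 000 (see `jshape_scenario`): the one-sided frailty→SBP
  shift piles frail patients into the low categories, so crude and
  adjusted-logistic RR curves show an interior minimum, while CV-TMLE
  with history-derived frailty features recovers a monotone
  non-decreasing gradient. The scenario's true gradient (log-odds steps
  of 0.35 per category) is steeper than the default conditions because
  the demonstration runs at a fraction of registry scale: per-contrast
  noise shrinks as 1/√n, so the scaled-down design raises the signal
  rather than the sample size, and its histories are dense (mean ~25
  pre-entry visits, ten frailty-linked tokens with loading 3.0) so the
  coded record genuinely contains the confounder — the premise the
  comparison tests. These are direction-only stochastic checks; with the
  measured per-replicate success rates, occasional counts just below the
  expected values are within sampling variation.

## Numerical conventions and degenerate inputs

Newton targeting raises an explicit estimation error after 100
non-converged iterations; propensities at exactly 0 or 1 are rejected
(clipping must precede); initial risks are clipped to (1e−12, 1−1e−12)
before taking logits; a training fold containing a single exposure arm or
outcome class raises a degenerate-fold error rather than fitting; an
empty eligible cohort is an explicit error. Fold assignment, masking,
weight initialization and batch order all derive from configured seeds;
reruns under a fixed configuration are bit-identical. CSV round-trips use
`float_precision="round_trip"` so `read(write(x)) == x` holds exactly.

## Known limitations

Binary-outcome censoring treatment (no survival TMLE, no competing
risks); pairwise contrasts re-estimate the reference arm per contrast,
which costs efficiency; the transformer is desk-scale (no GPU, no
pretrained weights, float64 throughout) and the original architecture's
exact hyperparameters are not reproduced; MICE draws smoking imputations
from fitted class probabilities without a posterior draw of the
multinomial coefficients, slightly understating between-imputation
variance; the synthetic coding vocabulary is a toy stand-in for clinical
phenotype dictionaries.
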
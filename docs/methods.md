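# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions a maintainer needs.

## Outcomes and analysis populations

Two outcomes are analysed from one survey table of past-year smokers:

* **Motivation to stop (MTSS)** — a 7-level ordinal scale asked of current
  smokers only; recent ex-smokers are never assessed (structural, not item,
  missingness). The Brant test on cumulative binary splits rejects the
  proportional-odds assumption for these data, so the scale is collapsed to
  three categories (level 1 → *absence*, 2–3 → *unspecific*, 4–7 →
  *motivation*) and modelled by multinomial logistic regression with
  *absence* as reference. The MTSS analysis population is current smokers.
* **Past-year quit attempt (QA)** — the raw attempt count dichotomised to
  ≥ 1 vs 0, modelled by binary logistic regression on all past-year smokers
  (current + recent ex).

Mandatory covariates in every model: strength of urges to smoke (6
categories, reference *medium strong*) and calendar time (categorical year
for MTSS, mirroring year-wise contrasts; linear per-year for QA). The five
intersection covariates are age, sex, education, household income
(standardised 0–7 scale) and region of residence. Reference levels: male,
low education, rural, year 2016.

## Restricted cubic splines

Continuous covariates may enter linearly or as a restricted cubic spline
with k ∈ {3, 4, 5} knots placed at Harrell's default quantiles (type-7
linear-interpolation estimator). The basis is the truncated-power form
whose nonlinear columns are normalised by (t_k − t_1)²; the implied
function is linear beyond the boundary knots, which keeps tail
extrapolation sane. Pipeline default: rcs(4) for age, linear for income.
**Knots are frozen at learning-data quantiles** and reused for every
bootstrap replicate and for validation predictions; recomputing knots per
dataset would silently change the model between training and validation.

## Fitting

Maximum likelihood by Newton–Raphson with step-halving; convergence when
every score coordinate is below 1e-8 or the relative log-likelihood change
is below 1e-10; covariance = inverse observed information. Rank-deficient
designs raise; quasi-separation (any standardised coefficient beyond 15) is
flagged on the result, not penalised — the pipeline's models are far from
separation at the sample sizes involved. The multinomial fit maximises the
joint (K−1)·p-parameter likelihood with a full cross-contrast Hessian, so
its covariance covers between-contrast dependencies (needed by the
spline-contrast CIs). The imputation engine alone uses a tiny ridge (1e-6)
in its conditional fits so that rare-category dummies cannot break a chain
at small n. BIC = −2ℓ + p·ln(n).

## Multiple imputation

Chained equations, one independent chain per imputation, 10 sweeps by
default. Methods by type: predictive mean matching (Bayesian coefficient
draw, 5 donors, type-1 matching) for age and income; logistic draws for QA;
multinomial draws for education, region, urges and the collapsed MTSS.
The conditioning set is all analysis variables; the collapsed (not 7-level)
MTSS is imputed — the analysis model only uses the collapsed outcome, and
the sparse upper scale levels would destabilise a 7-category conditional
model — and only for current smokers. When MTSS serves as a *predictor* in
another variable's conditional model, recent ex-smokers enter as an
explicit "not assessed" category. Learning and validation data are imputed
in fully separate runs (m = 10 / m = 20 defaults) so validation-side
information cannot leak into model selection.

Scalar pooling follows Rubin's rules with Barnard–Rubin degrees of freedom
when a complete-data df is supplied (classic large-sample df otherwise; B=0
degenerates to a normal CI). Likelihood-ratio tests are pooled by
Meng–Rubin D3: LR statistics are recomputed at the across-imputation mean
parameters, the average relative increase in variance r̃ is formed, and
D3 = d̄_L/(k(1+r̃)) is referred to F(k, ν). With identical completed
datasets this reduces exactly to the single-dataset chi-square test.
Calibration checks show D3 is well calibrated when the imputation draws are
asymptotically proper (logistic/multinomial posterior draws; a controlled
experiment with analytically exact Bayesian imputation rejects at 7.5% at
α = 0.05), and conservative (≈ 2–3%) when PMM's donor matching adds extra
between-imputation noise — a documented property of PMM, accepted here
because PMM keeps imputed incomes on the observed support.

## Scoring rules

* **Brier score**: mean (y − p̂)²; proper for binary outcomes.
* **PDI**: for each category j, the probability that one randomly drawn
  member of each category is "won" by the true category-j member having the
  strictly highest predicted probability for j; ties at the maximum split
  credit 1/t, making the uniform predictor score exactly 1/K — a clean
  calibration point. Computed by a per-category sort-and-count scheme
  (binary searches over the other categories' sorted predictions),
  O(n log n) per category, verified to 1e-12 against exhaustive tuple
  enumeration.
* **Accuracy change** between learning and validation: relative drop in PDI
  for MTSS; for QA the Brier loss is mapped to the accuracy scale 1 − Brier
  before taking the relative drop. Positive = degradation.

## Model selection

Candidates = Cartesian product of the continuous covariates' allowed forms
× interaction subsets of size ≤ 1 from the 10 unordered pairs of the five
intersection covariates (hierarchy enforced; interactions multiply the full
column blocks of their member terms, e.g. rcs(4)-age × income contributes
3 product columns). Each bootstrap replicate draws n ids with replacement
(inner learning set); the out-of-bag ids are the inner validation set.
Every candidate is fitted on the in-bag rows (warm-started from its
full-data fit) and scored on the out-of-bag rows; scores are averaged over
the imputed datasets and the B replicates, and the winner is the candidate
with the best mean (highest PDI / lowest Brier). Replicates missing a
categorical level in the bootstrap sample are redrawn up to 10 times, then
skipped with a log entry. B defaults to 200 — selection noise on the mean
OOB score falls as 1/√B and fixed-dataset reruns at B = 500 reproduce the
same winners, so larger B mostly buys nothing at desk scale. For the QA
outcome a BIC-based backward elimination (interactions before main effects,
splines reduced to linear before a covariate may drop, base terms never
dropped) prefilters the model, and its result joins the candidate set.

A winner containing an interaction is finally tested against the same model
without it by the pooled (D3) LR test; the interaction is kept iff
p < 0.05. Bootstrap scoring inside the selection loop uses the first
`m_score = 2` imputed datasets (candidate *ranking* is extremely stable
across completed copies because imputation only perturbs the ~5% missing
cells); estimation, confirmation and pooling always use all m imputations.

### What out-of-bag selection can and cannot suppress

Selection by mean OOB score protects against fitting bootstrap-level noise,
but both the in-bag and out-of-bag sets are drawn from the *same* realised
dataset: an interaction that is spuriously present in the dataset as a
whole (a ~2-df LR fluctuation of p ≲ 0.01, which happens in a few percent
of null datasets per pair and so regularly somewhere among 10 pairs)
improves OOB prediction too and can win selection. Fixed-dataset reruns
with different bootstrap seeds and B up to 500 reproduce such winners,
confirming they are dataset-level, not resampling noise. In null
simulations at n = 9 000 an interaction-bearing candidate wins in roughly a
third of datasets, and the LR confirmation (whose p-value is
selection-biased) removes only part of that. The package therefore treats
the LR confirmation as essential, reports replicate-level score
distributions so near-ties are visible, and documents that the selector's
false-positive rate over a 10-pair search space is materially higher than a
nominal 5%. Detection of a real interaction of the generated magnitude
(OR ≈ 0.67 on a ~2 600-person cell) at n = 9 000, B = 200 succeeds in
roughly three quarters of runs.

## Effects and external validation

Pooled OR tables exponentiate Rubin-pooled log-odds; spline-coded
covariates are reported as contrasts at fixed values (ages 20–80 vs 20;
income 0.5–3.5 vs 0.5), with CIs from the linear-combination variance,
interaction partners held at their reference. Marginal surfaces are
average marginal predictions (marginal standardisation): grid covariates
are forced on every record and predictions averaged over the empirical
distribution of the rest, per imputation; point estimates and delta-method
variances are pooled on the logit scale so CIs respect [0, 1].
Predictions-at-means would answer a different question (a single synthetic
"average" respondent) and is not what the probability surfaces show.
External validation refits the winner on each learning imputation, predicts
every validation imputation using the Rubin point estimate of the
coefficients and the frozen learning-data knots, and reports the accuracy
change; both the in-sample learning score and the external score are kept
in the report.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions:

* age ~ truncated normal on [18, 99] whose *realised* mean/SD match
  46.8/16.7 (the underlying normal parameters are solved for, because
  truncation would otherwise shift the mean by ~1.5 years);
* income ~ gamma, moment-matched to mean 1.47 / SD 0.818 and redrawn into
  [0, 7] — gamma reproduces the margin's right skew (median < mean);
* sex, education, region, urges ~ categorical draws at the published
  margins renormalised over observed cells; survey year uniform 2016–2020;
  current-smoker probability 12 784/13 245;
* MTSS: 3-category multinomial logit. Categorical effects are the
  published pooled log-ORs. The *motivation* contrast carries a smooth age
  bump f(age) on an rcs(4) basis (knots 25/40/55/75) fitted by weighted
  least squares to the published age contrasts with a monotone-smoothed
  tail, multiplied by (1 − 0.30·income) plus a −0.30 per-unit income main
  effect: a true age × income interaction whose motivation probability
  peaks near age 40 for incomes ≲ 2 and flattens as income rises. The
  3-category draw is then expanded to 7 levels with conditional
  proportions from the published level frequencies. Intercepts are
  calibrated once so the collapsed shares among current smokers are
  47.2/36.9/14.3 (observed-cell normalised);
* QA: logistic with the published log-ORs (time 0.77 per year; age 0.95
  per *decade* — a per-year reading would halve the odds across 14 years,
  implausibly steep against the published gentle age gradient; exposed in
  config), including the sex × education interaction (0.94 / 0.67);
  intercept calibrated to 18.3% prevalence. Positive counts expand to
  {1, 2, 3} with proportions (0.7, 0.2, 0.1) — plumbing only, the analysis
  uses the binary recode;
* missingness: per-variable MAR logits at the published marginal rates
  (education 1.4%, urges 1.2%, MTSS 1.5% of current smokers — the
  published 4.8% of past-year smokers is reproduced once the structural
  recent-ex missingness is added — QA 4.6%, income ≈ 0), plus a +0.5
  log-odds increment for male × high-education respondents on the
  smoking-habit variables (selective non-response).

Not emulated: the bi-monthly wave structure, survey weights, pandemic-era
waves, household-composition income equalisation (income is generated
already standardised), and any covariate correlation beyond what the
outcome models induce (covariates are drawn independently). Passing tests
therefore demonstrate the *machinery* — margin fidelity, estimator
correctness, calibration, selection behaviour — under a faithful but
simplified data-generating process, not reproduction of the original
survey's numeric estimates, which would require the third-party data.

## Numerical conventions and degenerate inputs

The 70/30 split size uses exact rational arithmetic with round-half-to-even
(13 245 × 0.7 → 9 272); softmax probabilities are computed max-shifted;
log-likelihoods use log1p-safe forms; score ties in selection break toward
the earlier (simpler-ordered) candidate; `count_full_strata` validates
positive integer level counts; zero-rate missingness and zero-missing
imputation are exact no-ops; an imputation request with m = 1 is refused.

## Problem sizes in the shipped test suite

Simulation-based tests run at desk scale: type-I calibration at 500
replicates (n = 500–1 000, m = 5), parameter recovery at n = 50 000 with
m = 4 imputations, interaction detection/suppression at n = 9 000, B = 200
over 8 seeded runs per arm, and pipeline stability at the full study size
over 5 seeds with B = 50, m = 2 and a 2-pair interaction pool. The
acceptance script uses B = 100, m = 3 for the study-scale pipeline run and
6 runs per arm of the detection experiment.
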
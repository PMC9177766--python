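# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical conventions, and the design decisions taken where
the design was genuinely open. It states no empirical claim that the test
suite or `scripts/acceptance.py` does not itself compute.

## The prediction target and the two kinds of uncertainty

The package predicts, for one surgical case, a *distribution* over the
probability of in-hospital death (death before day 60; patients still in
hospital on day 60 are treated as discharged alive). The distribution
aggregates two distinct sources of uncertainty:

* **Coefficient (epistemic) uncertainty** — the finite-sample imprecision
  of the fitted model, represented by a Gaussian approximation to the
  posterior over the penalized GAM's coefficients. For a case whose
  covariates are all observed, the spread of the predicted risks is a
  credible interval for that covariate profile's mortality risk.
* **Missing-covariate uncertainty** — when lactate or albumin has not been
  measured, plausible values are drawn from dedicated imputation
  sub-models and propagated through the risk model, widening the credible
  interval toward a prediction interval. This covers only variables that
  are measured in some cases and unmeasured in others; determinants of
  risk that are *never* measured are outside the model, as is uncertainty
  over the model specification itself.

## Risk model

Binomial GAM with a logit link over 21 covariates (ages through surgical
indication, plus lactate/albumin missingness indicators).

* **Splines.** Continuous covariates use 10 B-spline basis functions of
  degree 2 with linearly-spaced knots spanning the training range
  (boundary knots replicated). Inputs outside the knot range are clamped
  to it — deliberately consistent with Winsorization, so prospective
  predictions never extrapolate the spline tails.
* **Discrete covariates.** Dummy-coded with the base category excluded
  (avoiding the dummy-variable trap). Ordinal clinical grades (ASA 1–5,
  cardiovascular and respiratory status 0–3) are treated as unordered
  dummies in the risk model; the Glasgow Coma Score enters as a continuous
  spline because its summary statistics are numeric and its 13 levels
  would otherwise be data-starved.
* **Interactions.** Tensor products (column-wise products of the two
  marginal bases) for: heart rate × arrhythmia, urea × creatinine,
  cardiovascular × respiratory status, and CT-performed × each of
  peritoneal soiling, malignancy, indication. The CT interactions encode
  that predicted operative findings are more reliable when cross-sectional
  imaging backs them.
* **Penalties.** Spline terms carry a second-difference (P-spline)
  penalty on their coefficients — the discrete analogue of an integrated
  squared second derivative, whose null space is the linear functions, so
  increasing it drives a term toward a straight line. Categorical terms
  carry an L2 penalty on the inter-category contrasts; tensor terms carry
  the Kronecker sum of their marginal penalties. Default weights are
  spline 10, categorical 1, tensor 10 (unitless, on the coefficient
  scale). These defaults were fixed at design time as mild regularisation
  for cohorts in the 10⁴–10⁵ range; the original workflow tuned such
  penalties manually against partial-dependence plots, which is not
  automatable, so the package instead ships fixed defaults, full per-term
  overrides in `GamSpec`, and an optional generalized-cross-validation
  search over a global multiplier (`gam.choose_penalty_multiplier`; GCV
  score n·D/(n−edof)²). In our synthetic experiments the GCV profile is
  nearly flat, so it is an option, not the default.
* **Fitting.** Penalized maximum likelihood by iteratively reweighted
  least squares; convergence when the relative change of the penalized
  log-likelihood falls below 1e-6, capped at 100 iterations (a
  non-converged fit is returned flagged, with a warning). A 1e-8 ridge
  stabilises the normal equations. The coefficient covariance is the
  inverse penalized information matrix at convergence — the standard
  Bayesian-approximation view of a penalized GLM.
* **Pooling.** One fit per completed dataset, combined by Rubin's rules:
  pooled coefficient = mean; pooled covariance = mean within-fit
  covariance + (1 + 1/m) × between-fit coefficient covariance. The pooled
  diagonal therefore never falls below the mean within-fit diagonal.
* **Backward elimination** removes, iteratively with refitting, the
  candidate variable with the smallest per-column-normalised joint Wald
  chi-square over *all* of its design columns, tensor blocks included, so
  a variable's main effect and interactions are judged together.

## Two-stage multiple imputation

Stage 1 covers the routinely-collected covariates, which are assumed
missing at random given the other covariates and the outcome. Because this
stage runs only at fit time, the outcome is included in the conditional
models (excluding it would bias covariate–outcome associations toward
null). Chained equations run 10 cycles in order of increasing missingness:
Bayesian linear-regression draws (σ² from its scaled inverse-χ²
conditional, β from N(β̂, σ²(XᵀX)⁻¹), then the predictive normal) for
continuous variables; posterior-approximate logistic draws for binary
ones; ordinal grades are drawn linearly, then rounded and clipped to their
range — a pragmatic compromise in place of ordinal conditionals.
Continuous draws are clipped to the variable's plausible physiologic
range. Nominal variables (indication, soiling, malignancy) are then drawn
from multinomial-logistic conditionals — probabilistic draws, never the
modal category. The first-stage count `m` defaults to the
percent-incomplete rule: ⌈100 × fraction of cases incomplete for any
routine covariate⌉, minimum 1.

Stage 2 covers lactate and albumin, which are frequently unmeasured at
assessment time. Each completed dataset gets Gaussian GAM sub-models for
the two labs, fitted on the cases where the lab was observed; lactate is
modelled on the log scale (right-skewed marginal) and back-transformed on
draw. Each completed dataset then receives `k` (default 3) imputations:
one coefficient vector sampled from the sub-model's approximate posterior
per draw, plus residual noise — the full posterior predictive, since
proper imputation requires both components; either can be switched off in
`ImputationConfig` for sensitivity work. Drawn values are clamped to the
lab's training Winsor thresholds. By default the outcome is *excluded*
from the lab sub-models so they can run prospectively, before the outcome
exists; the sensitivity toggle restores it.

At prediction time the first-stage machinery is bypassed (routine
covariates must be supplied — only labs are imputed prospectively), and
the bundle carries Rubin's-rules-pooled lab sub-models (pooled across the
m per-dataset fits). The full m × k draw budget is preserved: a case gets
m × k lab-coefficient draws and, for each, `n_coef_draws` (default 5)
risk-model coefficient draws — 28 × 3 × 5 = 420 samples under the default
configuration, for complete and incomplete cases alike (complete cases
simply repeat the same completed version, so their spread reflects
coefficient uncertainty only).

## Preprocessing

Continuous variables are Winsorized at the training 0.1 and 99.9
percentiles (linear interpolation between order statistics — the
percentile convention used throughout the package), except age, which is
clamped above only. Thresholds are refit in every cross-validation round
on development cases and applied, frozen, to validation and prospective
inputs. Implausible values (outside per-variable physiologic ranges
configured in `VariableSpec`) are redacted to missing before imputation.
Raw ECG categories collapse to a binary any-arrhythmia flag; raw surgical
indications collapse to the 13 commonest plus "other", with the empty set
and multiple simultaneous indications mapping to missing (to be imputed).
Lactate/albumin missingness indicators are set *before* any imputation and
serve as model covariates, testing whether being measured at all carries
prognostic information.

## Validation harness

Cross-validation is grouped by hospital: 80% of hospitals develop, 20%
validate, repeated 120 times by default, so validation approximates
deployment at unseen centres. Every round refits thresholds, imputers and
the GAM on development cases only (the tests verify bit-identical refits
when validation data are tampered with). Validation cases missing any
baseline covariate (or any routine input the distributional model needs)
are excluded so both models are scored on identical cases; labs may still
be missing there and are imputed prospectively.

Scores: AUROC as pairwise concordance with ties at ½; Tjur's coefficient
(mean risk among events minus non-events); log loss with natural logs and
probabilities clipped to [1e-15, 1−1e-15]; Brier score. For the
distributional model each sampled-risk column is scored as a point
prediction and the scores averaged across columns. Calibration: a logistic
regression of the outcome on a 10-spline basis of logit(risk) (penalty 1)
gives a smooth curve; the mean absolute calibration error averages
|curve − identity| over 100 equally-spaced points spanning the central 99%
of predictions, weighted by the empirical density of the predictions —
dense regions dominate, and the sparse extremes (where calibration cannot
be assessed) are excluded. Cross-validation scores are summarised by the
median and the 2.5th/97.5th percentiles, and model comparisons are paired
within rounds before aggregation.

The baseline comparator is a refit complete-case logistic regression with
quadratic terms for continuous covariates on a configurable covariate
list. It stands in for the incumbent point-estimate calculator, whose
exact published equation is external to this package; as in the original
validation design, the comparison is against a *refit* baseline.

## Synthetic cohort generator

The generator emulates the study conditions: Table-level marginal
medians/IQRs (log-normal for the right-skewed labs — lactate, creatinine,
urea, white-cell count — normal otherwise, parameterised via
IQR = 1.349σ), latent-threshold ordinals and nominals, ~11.3% mortality
(the generative intercept is calibrated by root-finding), 186 hospitals
with Dirichlet-multinomial size variation and N(0, 0.1²) intercept
offsets, and the study's per-variable missingness rates. Covariate
correlation comes from a single latent severity factor mixed into each
variable's standard-normal driver (which preserves the marginals exactly);
severity loads on ASA, lactate, GCS, heart rate and others, which is what
makes missing-at-random imputation informative. The generative risk is a
known smooth logistic function with U-shaped sodium and potassium terms,
log-linear lactate, a heart-rate×arrhythmia and a urea×creatinine
interaction — all representable by the model's basis, as a recovery
benchmark should be.

Lab missingness under the `MAR-on-severity` mechanism depends only on an
observed-covariate severity proxy (ASA, heart rate, GCS — never the lab's
own value), with sicker patients *more* likely to be measured; the
marginal rate is calibrated by root-finding. Indication missingness is
injected completely at random, as its real-world mechanism is a
preprocessing artefact of unknown form.

What the generator does **not** emulate: the joint dependence structure of
real registry data beyond the single severity factor, temporal trends in
mortality or in albumin recording (dates were unavailable even in the
source study), repeat-laparotomy dependence between cases, and
hospital-level differences in measurement practice. Passing tests
therefore demonstrate the *machinery* — propriety of the imputation,
correctness of pooling and scoring, leakage-free validation, qualitative
uncertainty behaviour — not clinical performance on real data.

## Problem sizes used by the test suite

The suite validates at sizes chosen to make each property measurable while
keeping a full run in tens of seconds to a few minutes: structural
arithmetic at n=1,200 with the full 28×3 imputation grid; parameter
recovery and calibration of the generator's own risks at n=20,000 (the
fitted logit surface is compared with the generative truth on per-variable
grids spanning the central 99% of the training range with other covariates
at reference values — training median for continuous, base category for
discrete — since the model deliberately saturates outside the training
support); uncertainty-monotonicity and the case study on a bundle trained
at n=12,000 (at much smaller sizes coefficient uncertainty swamps the lab
signal and the qualitative contrasts are not identifiable); harness
integrity with 12 grouped splits over 20 hospitals at n=4,000 with a
reduced covariate set.

## Known limitations

* The coefficient posterior is a Gaussian (Laplace-type) approximation;
  heavy-tailed posteriors under separation or sparse categories are not
  captured.
* Ordinal variables are imputed by round-and-clip rather than ordinal
  conditionals, and imputed categorical draws condition only on numeric
  covariates.
* The rdr stratification by *natural* missingness group confounds case mix
  with imputation uncertainty when missingness tracks severity; the causal
  effect of missingness on uncertainty is only identified by blanking labs
  on the same cases, which is how the tests measure it.
* Backward elimination uses Wald statistics on the penalized fit, which
  are approximate for heavily-penalized terms.
* Hospital effects exist in the generator but not in the model (as in the
  original design); predictions are population-level.
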
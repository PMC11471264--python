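# Methods

This note documents the statistical model behind `income_qba`, the choices
made where the method leaves room, and what the synthetic validation does
and does not demonstrate.

## Setting and notation

A cohort of n individuals carries an observed exposure J ∈ {1..5} (the
neighbourhood income quintile; 1 = lowest income), optionally the true
exposure K ∈ {1..5} (household income quintile), a binary outcome Y
(death within five years of diagnosis), and covariates age, sex and rural
residence.  Misclassification of K by J may be *differential*: the
agreement pattern differs between survivors and decedents, so all bias
parameters are stratified by Y.

The bias parameters are the predictive values

    P_y[j, k] = Pr(K = k | J = j, Y = y),

25 cells per outcome stratum: 5 positive predictive values on the diagonal
and 20 negative predictive values off it.  Predictive values (rather than
sensitivities/specificities) are the natural parameterization when the
validation data are a cross-tabulation of J by K within the study cohort
itself, and they can be transported to an external cohort only when that
cohort has a similar exposure marginal, outcome prevalence and
misclassification predictors.

## Step 1 — estimating the bias parameters

**Crude.**  Row proportions of the J×K cross-tabulation within each outcome
stratum.  Per-cell 95% intervals use the Wilson score method, which is
well-behaved for the moderate cell proportions (0.07–0.37) that occur here.

**Covariate-adjusted.**  Within each outcome stratum, a multinomial logistic
regression with K as the 5-category response (reference: quintile 5) and
predictors: indicators for J = 1..4 (reference J = 5), age (centred at the
stratum mean, for optimizer conditioning), sex, and rural residence.  The
predictive-value matrix is the softmax of the fitted linear predictors
evaluated at each observed quintile with covariates held at their
stratum-specific means; binary covariates are held at their sample
proportions rather than rounded, since the fitted model is linear in them
on the logit scale and the prediction point should represent the stratum.

Interval bounds for adjusted values are a delta-method approximation on the
softmax transform using the full coefficient covariance; a parametric
bootstrap (draws of the coefficient vector from its asymptotic normal,
default 2,000) is available as a cross-check and agrees with the delta
method within a few percent of the half-width at the bundled sample sizes.
The source validation study does not state how its CIs were computed; the
delta-method default is this package's documented choice.

When J and K agree perfectly the multinomial likelihood separates and the
maximum-likelihood fit diverges; the fitter detects this (non-convergence
or non-finite coefficients) and refuses with a hint to use the optional
ridge penalty — a per-parameter L2 term solved by penalized Newton
iterations with covariance from the penalized observed information.  The
penalty defaults to off and its use is reported through the fit object.

Equivalence anchor: with the observed-quintile indicators as the only
predictors the multinomial model is saturated, and its predicted matrix
equals the crude row proportions to optimizer tolerance.  This identity is
tested and is the module's primary correctness check.

## Step 2 — probabilistic bias analysis

**Beta parameterization.**  Each predictive-value cell with point estimate
x and 95% bounds (L, U) becomes Beta(α, β) with

    sd = (U − L) / (2·1.96),   ν = x(1−x)/sd² − 1,   α = xν,   β = (1−x)ν.

Algebraically the beta mean is exactly x and the beta variance exactly sd²,
so the construction is an exact moment match, valid whenever sd² < x(1−x)
(wider intervals are rejected with advice to narrow them or treat the cell
as a point value).  Cells with zero-width intervals pass through unsampled.

**Row handling.**  The 25 cells are drawn independently and each row is
renormalized to sum to one.  The per-cell beta construction does not define
a joint distribution on the simplex; renormalization is the minimal
completion that guarantees a proper categorical distribution, and the
induced bias is small (the mean of sampled matrices stays within 0.01 per
cell of the point estimates at the bundled interval widths — tested).  A
per-row Dirichlet alternative (concentration matched to the median cell
α+β) is available behind a flag but off by default, since the per-cell
betas are the stated construction.

**Reassignment.**  Record-level: each record draws its bias-adjusted
quintile from row J of the sampled matrix for its outcome stratum — ten
(J, Y) combinations.  Aggregate expected-count reallocation would give the
same distribution for the unadjusted effect model but would not extend to
covariate-adjusted per-iteration fits, and record-level imputation is the
method as practiced.

**Effect estimation and total error.**  On each reassigned dataset the
quintile contrasts k vs 5 are estimated by modified Poisson regression
(log-link Poisson on the binary outcome, HC0 sandwich variance — no
small-sample correction, immaterial at these n).  For the unadjusted model
with a categorical exposure the fit is available in closed form: the RR is
the ratio of stratum risks and the HC0 robust variance of the log RR is
(1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀) exactly; the engine uses the closed form on
the unadjusted path (the equality with the GLM is tested to 1e-6) and fits
the GLM per iteration when covariate adjustment is requested.  Random error
is then added as

    log RR_total = log RR_bias-adjusted − z·SE,   z ~ N(0, 1),

with SE the iteration's robust standard error.  The source description
says only that a standard-normal draw is incorporated; scaling by the
iteration SE is the established probabilistic-QBA convention and is this
package's documented interpretation.

**Summaries and reproducibility.**  Per contrast, the 50th percentile of
the RR distribution is the estimate and the 2.5th/97.5th percentiles the
95% simulation interval.  Iterations are driven by RNG substreams spawned
from the master seed, so results are bit-reproducible and order-independent.
Iterations whose reassignment empties a quintile (or leaves a quintile with
no deaths) are discarded and counted; more than 5% failures aborts the run.
Default iteration count is 10,000; the bundled analyses use 2,000, at which
the Monte Carlo error of the median is ≈0.002 on the RR scale — negligible
against the simulation interval width of ≈0.26.

## Step 3 — comparison

Validation mode compares three estimates per contrast: the naive
observed-exposure RR (what a proxy analysis reports), the bias-adjusted
median with its SI, and the gold-standard true-exposure RR; unadjusted and
covariate-adjusted versions of each where covariates exist.  Application
mode — the intended reuse, when only the observed exposure is available —
skips the gold standard and takes the predictive values from an external
table such as the bundled published one.  Grouped analyses (e.g. by region)
repeat all steps per group with no pooling or shrinkage.

## Synthetic cohorts

The generator specifies the *forward* direction Pr(J | K) — predictive
values depend on the exposure marginal and the outcome model, so they
cannot be primitives of a generative model — and the implied predictive
values are recovered analytically by Bayes' rule:

    Pr(K = k | J = j, Y = y) ∝ q_k · M[k, j] · d_k^y (1 − d_k)^(1−y),

where q is the quintile marginal, M the base misclassification matrix and
d_k the covariate-marginal death probability for quintile k (exact because
the risk model is linear in the covariate multiplier and, in the default
configuration, the mechanism is covariate-free, making J independent of Y
given K).  This analytic oracle anchors the parameter-recovery tests.

Default study conditions: n = 21,560; uniform quintile marginal; age
truncated-normal 66 (SD 12.5) on [35, 100] (the cohort is adults with
colorectal cancer); 55.3% male; 23.7% rural; covariates mutually
independent.  The base matrix is geometric-decay, row k ∝ r^|j−k| with r
chosen so the middle row's diagonal is 0.31, giving diagonal agreement
0.31–0.38 — loosely calibrated to the validation table, whose exact cells
are reproduced by the bundled fixture rather than by the generator.  The
outcome model is log-linear with quintile RRs (1.46, 1.374, 1.188, 1.118,
1.0) — the gradient the validation counts imply — modest covariate effects
(0.015/year age, 0.10 male, 0.05 rural on the log-risk scale), and a
baseline risk solved numerically so the analytic overall 5-year mortality
is 0.423, the value implied by the validation table's cells.  (The source
cohort reports 49.2% mortality in text; its printed cells imply 42.3%, and
the generator follows the cells.  The discrepancy is documented, not
reconciled.)  Misclassification is nondifferential by construction within
stratum in the default configuration; an optional covariate shift (e.g.
rural residence adding log-odds mass to off-diagonal cells) makes it
covariate-dependent, in which case the analytic oracle refuses and implied
values must be obtained empirically.

What passing synthetic tests show: the estimators recover known predictive
values and known effect gradients, attenuation behaves as theory predicts,
and the QBA pipeline is internally consistent end-to-end.  What they do not
show: robustness to covariate dependence structures, geographic clustering,
non-proportional covariate effects, or transportability of predictive
values across populations — none of which the generator emulates.

## Numerical choices and edge cases

- Quintile orientation is fixed (1 = lowest income) and validated at I/O.
- Records expanded from printed counts carry no covariates; every
  covariate-adjusted operation refuses them explicitly rather than imputing.
- Printed predictive-value tables are row-renormalized on load (printed
  percentages carry rounding); interval bounds are kept as printed.
- Row-stochasticity tolerances: 1e-9 for estimated matrices, machine-exact
  after explicit renormalization.
- The all-zero sampled row (possible only with extreme beta draws) is
  resampled, bounded at 100 attempts.
- Percentiles use NumPy's default linear interpolation.

## Known limitations

- Predictive-value bias parameters are outcome-specific: they transport
  only to cohorts with a similar exposure marginal, outcome prevalence and
  misclassification predictors, and only for this outcome definition.
- The binary 5-year mortality outcome sidesteps censoring; no time-to-event
  QBA is provided.
- Outcome misclassification, non-beta priors on the bias parameters, and
  joint uncertainty across cells beyond the optional Dirichlet are out of
  scope.
- The delta-method CIs for adjusted predictive values are asymptotic;
  in very sparse strata prefer the bootstrap flag or the ridge penalty.
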
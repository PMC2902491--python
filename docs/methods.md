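# Methods

## The model

A semicontinuous response `Y_ij >= 0` (subject `i`, occasion `j`) is
modeled in two coupled parts. The *occurrence* part is a binary GLMM:
`P(Y_ij > 0 | tau_0i) = Phi(x1_ij' beta1 + tau_0i)` (probit link; logit
selectable). The *severity* part models the log of positive responses
with a skew-normal distribution, `log Y_ij | Y_ij>0 ~ SN(x2_ij' beta2 +
tau_1i, sigma, delta)`. The subject intercepts `(tau_0i, tau_1i)` are
bivariate normal with covariance `S`; their correlation expresses that
subjects prone to *having* symptoms also tend to have *worse* symptoms.

Conventions that matter:

* **Direction of the link.** The linear predictor drives the probability
  of a *positive* response. "Probability symptom free" is reported as its
  complement. This is the sign convention under which a positive
  coefficient on a risk factor means more (and worse) symptoms in both
  parts.
* **Severity on the log scale.** The severity likelihood is the density
  of `log Y`, without the `1/y` Jacobian. Deviance, AIC and BIC are
  therefore directly comparable between the skew-normal severity model
  and its `delta = 0` (lognormal) submodel — which is the comparison the
  likelihood-ratio test makes — but not with models expressed on the
  original response scale.
* **Skew-normal parameterization.** We use the Sahu–Dey–Branco form,
  `Y = mu + delta|Z0| + sigma Z1`: closed-form moments
  (`E Y = mu + delta sqrt(2/pi)`, `Var Y = sigma^2 + delta^2 (1-2/pi)`),
  exact reduction to the normal at `delta = 0`, and a non-singular
  information matrix at `delta = 0`. The mapping to the Azzalini direct
  parameterization is `lambda = delta/sigma`, `omega^2 = sigma^2 +
  delta^2`. The LRT for `delta = 0` is referred to chi-square(1); note
  the caveat that `delta = 0` remains the symmetry point of the family,
  so the test is best read alongside the Wald test and the information
  criteria.
* **BIC sample size** is the number of subjects (the independent
  sampling units), not the number of observations.

## Marginal likelihood and quadrature

Each subject contributes a 2-D integral of its conditional likelihood
against the bivariate-normal random-effect density. With `tau = L u`
(`L` the Cholesky factor of `S`) the integral is computed on a
Gauss–Hermite product grid in `u`, with log-sum-exp accumulation (a
51-occasion subject's conditional likelihood underflows in raw space).
Because `L` is lower triangular, the occurrence part depends only on the
first node index and the severity part is evaluated only at positive
observations, which keeps the cost at `q*N + q^2*N_pos` per evaluation.

Two rules are available:

* **Non-adaptive** (`QuadratureRule(n_points=21)` default for plain
  evaluation): nodes at the prior scale. Fine for short series and for
  oracle comparisons.
* **Adaptive** (`QuadratureRule(7, adaptive=True)`, the *fitting*
  default): per subject, a damped Newton iteration (run vectorized
  across all subjects; the conditional posterior is strictly concave in
  `u` for both links) locates the posterior mode of `u`, and the rule is
  recentered and rescaled by the Cholesky factor of the inverse
  curvature. This matters at the design sizes of interest: with 50
  occasions per subject the conditional posterior is several times
  narrower than the prior, and prior-scaled rules still showed
  log-likelihood oscillations of order 1 at 61 points per dimension,
  biasing variance components downward by 15–40%. The adaptive 7-point
  rule matches a direct 2-D quadrature oracle to ~3e-6 on test problems
  and removes that bias.

During optimization the recentering is held fixed within each
optimization pass — making the analytic gradient exact for the objective
actually minimized — and refreshed between passes until the fixed and
refreshed objectives agree (at most 8 cycles; usually 2–3).

## Optimization

Parameters are estimated on an unconstrained scale: `(beta1, beta2,
log sigma, delta, log s11, log s22, z)` with `s12 = tanh(z)
sqrt(s11 s22)`, so every iterate has a positive scale and a positive
definite `S`. The optimizer is L-BFGS-B with the analytic gradient
(verified against central finite differences to 1e-8 relative in the
test suite); convergence requires a gradient norm below `1e-6` relative
to the objective magnitude.

Starting values are produced in two stages: (1) the no-random-effects
model — an ordinary probit/logit regression for the occurrence part and
a skew-normal regression on the log positive responses; (2) random
effects started at `s11 = s22 = 0.5`, `s12 = 0`.

Two non-convexities of the skew-normal likelihood are handled
explicitly:

* `delta = 0` with OLS-centered residuals is an *exact stationary point*
  (the `delta`-score is proportional to the mean residual). The stage-1
  skew-normal regression therefore starts `delta` at its
  method-of-moments value (inverting the moment equations at the sample
  variance and skewness), and if a full fit still lands at
  `|delta| < 0.05` it is retried from `delta = +-sigma_hat` displaced
  starts.
* The likelihood is *reflection-bistable*: mirroring `delta -> -delta`
  while shifting the severity intercept by `2 delta sqrt(2/pi)` lands
  near a second local maximum. Every fit is re-run from the mirrored
  solution and the better deviance is kept, so the reported fit is the
  global maximizer. (On symmetric data the two modes are nearly tied and
  the chosen sign follows the sample's finite skew.)

Standard errors: central-difference Hessian of the marginal negative
log-likelihood at the optimum (step `~6e-6 * (1+|theta|)`, differencing
the analytic gradient), inverted and mapped to the natural scale by the
delta method. A singular Hessian downgrades to a pseudo-inverse with a
warning, and negative variance estimates are reported as missing rather
than fabricated.

## Robustness simulation

`simulation` generates from a probit/log-*beta* model: the positive
part's log follows a four-parameter beta on `[Theta, Theta + scale]`,
`Theta = alpha1 + beta1_x x + tau_1`, `eps ~ Beta(a, b)`. Default
settings are the study conditions: 200 subjects × 50 occasions,
`alpha0 = -1`, `beta0 = 2.5`, `alpha1 = -20`, `beta1 = 0.75`,
`s11 = 1`, `s22 = 0.2`, `s12 = 0.2`, `scale = 30`, `x ~ Bern(0.03)`
(a rare viral-week flag), with shapes `(130, 70)` (skewness −0.0883),
`(100, 100)` (0) and `(70, 130)` (+0.0883). `alpha1` and `scale` place
the positive response between `e^-20 ~ 0` and `e^10`, emulating a
continuous outcome bounded below at zero. Replicates use independent
child streams spawned from the master seed, so extending the replicate
count never changes earlier replicates; results are bit-reproducible.
The bias/MSE table tracks the probit intercept and slope, `s11`, the
severity slope, `s22` and `s12`; the severity *intercept* of the
generating log-beta model lives on a different scale than the fitted
skew-normal location and is archived but not tabulated. Non-converged
replicates are excluded and counted.

Observed behavior worth knowing: fitting the skew-normal model to
symmetric beta data leaves `delta`-hat *bimodal* (a reflection pair near
±0.5 whose sign follows each sample's finite skew); its mean across
replicates is therefore near zero with a large spread, and any single
reported mean for this case is sensitive to the optimizer's tie-break.
On negatively skewed beta data `delta`-hat concentrates around −0.7.

## Diary preprocessing and the synthetic cohort

Daily scores are the sum of six 0–4 symptom ratings (missing if any
component is missing). Weeks run Sunday–Saturday over the 2004 study
year (week 1 starts 2004-01-04; 51 full weeks); a weekly average is the
mean of observed days when at most two of seven are missing, else
missing — averaging the observed days is identical to the
impute-by-weekly-average rule, since imputing a mean leaves the mean
unchanged. Week-level viral status is the OR over the week's days, with
untested days negative. Any incomplete symptom panel makes the whole
day missing (the conservative reading of the missing-day rule).

The real cohort is not publicly deposited, so `synthesize_diary`
generates diaries with the same *shape*: ~75% zero weeks (the probit
baseline is solved so the marginal zero fraction equals the configured
value under heterogeneity), right-skewed positive severities from the
fitted model family (log-skew-normal weekly means, `sigma = 0.6`,
`delta = -0.8`, `s11 = 1`, `s22 = 0.2`, `s12 = 0.2`), ~3% viral weeks
with strong positive effects in both parts (+2.0 probit, +0.7
log-severity), a cosine seasonal term, 135/190 asthmatics, and
completely-at-random missing days (2%). Daily totals are Poisson draws
around the weekly mean, split across the six symptoms by capped urn
draws so every panel is a valid set of ratings. What passing tests on
this generator do **not** show: robustness to informative missingness,
reporting-mode effects, enrollment/dropout structure, or any feature of
the real cohort beyond the moments listed above — its job is pipeline
testing and effect-direction recovery.

## Problem sizes used by the test suite

The suite runs the replicated checks at sizes chosen to keep the whole
run in a few minutes while leaving the *per-replicate* design at full
scale (200 subjects × 50 occasions): parameter recovery uses 50
replicates with tolerance `3 * sd/sqrt(50)` computed from the run
itself; the negatively skewed robustness scenario uses 50 replicates and
the symmetric one 25, compared against the published 200-replicate table
with `+-3 sqrt(MSE_published/R)` bands. The full 200-replicate studies
are a CLI invocation away (`snhurdle study`), at roughly 1.5 s per
replicate fit.

## Known limitations

* No random time slope (a trivariate-normal extension) and no serial
  correlation beyond what the random intercepts induce; no
  interval-censored zeros; no Box–Cox severity alternative.
* The LRT for `delta = 0` is treated as a regular chi-square(1) test;
  users worried about the symmetry point should corroborate with AIC/BIC.
* Adaptive quadrature assumes a unimodal conditional posterior per
  subject (guaranteed concave in `u` here, but heavy-tailed severity
  misspecification can make few-point rules optimistic).
* The probit-side parameters of the robustness study acquire a small
  (+0.05 on a 2.5 slope) bias under severity misspecification via the
  correlated random effects; this is a property of the exact MLE, not of
  the quadrature.
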
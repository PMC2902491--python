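# snhurdle

Two-part (hurdle) mixed models for **zero-inflated continuous repeated
measures**: a probit (or logit) model for whether a response is positive,
coupled with a **log-skew-normal** model for the severity of positive
responses, linked by correlated subject-level random intercepts.

The motivating setting is longitudinal symptom-diary data: weekly average
respiratory-symptom scores in a pediatric cohort, where ~75% of
subject-weeks are exactly zero (no symptoms) and the positive scores form
a right-skewed continuous distribution. The same structure appears in
health-cost, consumption and exposure data.

## Model

For subject *i* at occasion *j*, with response `Y_ij >= 0`:

```
P(Y_ij > 0 | tau_0i)       = Phi(x1_ij' beta1 + tau_0i)
log Y_ij | Y_ij > 0, tau_1i ~ SN(x2_ij' beta2 + tau_1i, sigma, delta)
(tau_0i, tau_1i)            ~ BVN(0, S),  S = [[s11, s12], [s12, s22]]
```

`SN(mu, sigma, delta)` is the skew-normal distribution in the
Sahu–Dey–Branco parameterization, `Y = mu + delta|Z0| + sigma Z1` with
`Z0, Z1` iid N(0,1): it reduces exactly to `N(mu, sigma^2)` at
`delta = 0`, carries the sign of the skew in `delta`, and keeps the
Fisher information regular at `delta = 0`, so `H0: delta = 0` (i.e. "a
lognormal severity model is enough") is testable by ordinary Wald and
likelihood-ratio chi-square(1) tests.

Estimation maximizes the **marginal likelihood**: each subject's
conditional likelihood is integrated over `(tau_0, tau_1)` with adaptive
Gauss–Hermite quadrature (per-subject mode/curvature recentering;
vectorized across subjects with analytic gradients). AIC/BIC use the
number of subjects as the BIC sample size.

The package also ships the model's robustness study: generate data whose
positive part is a **four-parameter beta** on `[Theta, Theta + scale]`
(negatively skewed, symmetric, or positively skewed), fit the
probit/log-skew-normal model, and tabulate per-parameter bias and MSE
across replicates — plus a symptom-diary pipeline (daily 0–4 symptom
ratings, Sunday-to-Saturday weekly averaging with missing-day rules, and
a synthetic diary generator).

## Worked example

```python
import snhurdle as sh

truth = sh.ParameterSet(beta1=[-1, 2.5], beta2=[0.3, 0.75],
                        sigma=0.6, delta=-0.8, s11=1, s22=0.2, s12=0.2)
data = sh.simulate_probit_logsn(truth, 150, 40, p_x=0.05, seed=7)

fit = sh.fit_mle(data)
print(fit.summary())

fit_ln = sh.fit_mle(data, fix_delta=0.0)      # nested lognormal severity
stat, df, p = sh.lrt_delta_zero(fit, fit_ln)
print(f"LRT for delta=0: chi2(df={df}) = {stat:.2f}, p = {p:.2e}")
```

prints

```
Two-part probit/log-skew-normal mixed model
subjects: 150   observations: 6000

parameter                  estimate (se)
b1:intercept            -1.164 (0.079)***
b1:x                     2.386 (0.113)***
b2:intercept             0.216 (0.088)**
b2:x                     0.772 (0.059)***
sigma                    0.585 (0.041)***
delta                   -0.812 (0.087)***
s11                      0.811 (0.118)***
s22                      0.178 (0.034)***
s12                      0.186 (0.053)***

-2 Log Likelihood  7998.1
AIC                8016.1
BIC                8043.2   (sample size = number of subjects)
converged: True  iterations: 62  |grad|_inf: 1.09e-03

LRT for delta=0: chi2(df=1) = 11.37, p = 7.47e-04
```

Reading the table: `b1:x = 2.386` means the binary covariate (think: a
viral-positive week) sharply raises the probability of any symptoms —
the probability of being symptom free is `1 - Phi(eta)`; `b2:x = 0.772`
means it also raises the severity of symptoms when present. `delta`
recovers the negative skew of the generating model (truth −0.8), and the
LRT rejects the lognormal submodel.

## Command line

```sh
snhurdle fit        --input weekly.csv --output fit.json \
                    --binary-covariates viral,asthma --continuous-covariates viral
snhurdle simulate   --scenario negative_skew --output data.csv --seed 1
snhurdle study      --scenario negative_skew --output-dir study/ --n-reps 200
snhurdle synthesize --output diary.csv --n-subjects 190 --seed 1
snhurdle aggregate  --input diary.csv --output weekly.csv
```

Builtin study scenarios (`negative_skew`, `symmetric`, `positive_skew`)
are the three four-parameter-beta settings of the robustness study; any
flat YAML file with the same keys works too. Every stochastic command
writes its resolved configuration and seed next to its outputs.

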
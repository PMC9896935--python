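# Methods

## The measurement model

The SEM-based estimators treat biological age as a one-factor latent
variable. With J biomarkers `x_1..x_J` and `g(CA)` either CA (linear
form) or ln CA (log-linear form):

    x_j = nu_j + lambda_j * BA + eps_j,   eps_j ~ N(0, theta_j)
    BA  = b * g(CA) + zeta,               zeta  ~ N(0, psi)

Assumptions: a single latent dimension of deterioration; linear marker
response; Gaussian, mutually independent marker errors; `g(CA)` measured
without error and exogenous. Identification uses the reference-indicator
convention (`lambda_1 = 1`); the latent intercept is fixed at 0 because
with free marker intercepts it is not separately identified. Estimation
is maximum likelihood on the distribution of the markers conditional on
`g(CA)` (the fixed-x convention, equivalent to joint normal ML with the
exogenous moments saturated). Conditioning makes the linear and
log-linear forms comparable by AIC/BIC — the dependent data are the same
markers; only the regressor changes.

The optimizer is L-BFGS-B over `(lambda_2..J, b, log psi, log theta_j)`
with the analytic gradient, started from principal-axis estimates on the
age-partialled marker covariance, with up to five jittered restarts,
followed by Newton polishing on the analytic gradient. The polish
matters: the downstream invariances (rescaling a marker changes
`(nu, lambda, theta)` but leaves factor-score ranks and OF BA unchanged)
are identities *at the ML optimum*, and hold numerically to ~1e-6 in BA
units only when the gradient is driven near machine precision.

Factor scores are regression (expected a posteriori) scores,
`FS_i = E[BA | x_i, g_i]`; Bartlett scores are available behind a flag
(`score_method="bartlett"`). Fit statistics are the conditional
log-likelihood, AIC `= -2l + 2p`, BIC `= -2l + p ln n` with
`p = 3J + 1`, and the SRMR of the model-implied versus observed joint
covariance (correlation metric, diagonal included).

## Classic estimators

MLR and PCA are as conventionally defined (see README). Two choices are
deliberate:

* **PCA scaling.** BA is the standardized first component mapped to
  `mean(CA) + PC1 * SD(CA)`. Regressing CA on the component would shrink
  the BA variance below the CA variance; moment matching keeps the
  full spread, consistent with PCA-based BA having the *largest* ΔBA
  variance among the methods.
* **KD's s_BA.** The shrinkage variance defaults to
  `s_BA^2 = max(1e-6, mean[(BA_E - CA)^2] - ((1 - rbar^2)/rbar^2) * (CA_max - CA_min)^2 / (12 J))`
  with `rbar` the mean |marker-age correlation| — the sampling-noise
  correction uses the variance of a uniform age distribution. A
  user-supplied `s_ba2` overrides it.

A structural point worth knowing: when the KD calibration is fitted on
the same sample it scores, OLS of KD BA on CA has slope exactly 1 and
intercept exactly 0 — the per-marker OLS residuals are orthogonal to CA
with zero mean, and any fixed linear combination of them inherits that.
The identity-line behaviour of KD is algebra, not luck.

## Hazard modelling

The Gompertz proportional-hazards likelihood with right censoring is

    l = sum_i [ d_i * ln mu_i(t_i) - H_i(t_i) ],
    mu_i(t) = k * exp(alpha*CA_i + beta*t + x_i'theta)

with the baseline-age/duration constraint `alpha = beta` implemented as
one shared parameter (exact by construction, not a penalty).
Optimization runs over `(ln k, beta, theta)` with the analytic gradient
(BFGS plus a second polishing pass); `beta` is kept on the positive side
where the rate-of-aging interpretation lives. Standard errors are Wald
from the observed information (central finite differences of the
analytic gradient); `k`'s interval is back-transformed from `ln k`.
Whether the published analysis profiled the constraint or used full
information is unknowable from the text; observed-information Wald is
used here. AIC/BIC use n = subjects (not events).

The OD estimator reads the hazard-matching identity as: *null hazard at
age BA equals augmented hazard at the subject's actual (CA, FS)*. The
literal alternative — augmented hazard also evaluated at BA — degenerates
to 0/0 at `gamma = 0`, contradicting the required limiting behaviour
(BA -> CA), and is rejected. The identity then has the closed form given
in the README; a root-finder cross-check is part of the test suite. For
the "nonlinear" OD variant the factor scores come from the log-linear
SEM while the hazard stays Gompertz in age.

## Evaluation

* **E(65).** `E = int_0^omega S(t) dt` with
  `S(t) = exp(-(k/beta) e^{beta*age + phi*delta} (e^{beta t} - 1))`,
  adaptive quadrature (tolerance 1e-8) to `omega = 120 - age`; an
  exponential-integral closed form (`E1`) serves as an independent check.
* **AUC by specificity band.** The ROC (midrank tie handling) is
  integrated over false-positive rates `[1-hi, 1-lo]` with linear
  interpolation at the band edges, normalized by band width so a perfect
  classifier scores 1 on any band; the full band equals the Mann-Whitney
  rank AUC exactly.
* **ROC labels.** Death within a fixed follow-up horizon (default 20 y);
  subjects censored earlier carry no label and are dropped; the risk
  score is the model-predicted cumulative hazard at the horizon. This is
  a declared convention — other constructions (time-dependent ROC) are
  out of scope.
* **Disparity regressions.** OLS of ΔBA on CA, a female indicator,
  race/ethnicity dummies (reference: non-Hispanic white) and education
  dummies (reference: less than high school), reported per method with
  adjusted R², AIC, BIC.

## The synthetic cohort

The generator emulates exactly the structure the estimators assume: CA
uniform on 30–75 y; one latent factor linear in CA with Gaussian
disturbance; nine markers with loadings
(1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, −0.6, −0.8) — the two negative ones
mirroring markers such as expiratory volume and albumin that improve as
physiology worsens — unit residual SDs; and Gompertz mortality with
`k = 1e-4`, `beta = 0.09` and a latent effect `gamma = 1.5` per SD of the
latent, censored at 25 y (survival times by exact inverse-CDF sampling).
The structural scale is set by slope `b = 0.077` per year with the
disturbance SD tied to `psi = b*(age range)/sqrt(12)`, which makes CA
explain exactly half the latent variance and gives `psi = 1`; marker
reliabilities then span ~0.24–0.67, a realistic range for clinical
biomarkers. Optional per-group latent offsets (in years) inject known
disparities for recovery tests. Default n = 5,000.

What the simulator does **not** emulate: non-Gaussian and skewed marker
distributions, multiple latent domains, time-varying biomarkers,
competing risks, survey weighting, and mortality selection into the
baseline sample. Passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not
robustness to real-data violations of them.

## Numerical and testing choices

* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` sub-streams; identical seeds give
  bit-identical cohorts and pipeline artifacts.
* Degenerate inputs fail loudly: markers that are exact functions of CA
  (KD weights diverge), constant markers, constant factor scores,
  cohorts with zero events, empty post-filter cohorts.
* Eligibility filtering treats deaths from HIV/violence/accidents as
  censored at their observed duration (preserving exposure time, the
  standard competing-cause convention) rather than deleting the rows; a
  switch (`excluded_cause_action="drop"`) restores deletion.
* Parameter-recovery tests run 20 simulations at n = 5,000 and compare
  the mean estimate to the truth using a simultaneous 3-SE Monte-Carlo
  band across the ~11 free parameters — the family-wise strictness of a
  single 2-SE check; per-parameter 2-SE bands would reject a correct
  implementation roughly half the time by multiplicity alone.
* Problem sizes throughout the suite (n = 5,000 reference cohorts,
  n = 20,000 for the survival-time sanity check, 20-seed recovery loops)
  were chosen so Monte-Carlo error is small relative to the assertions
  while the whole suite stays fast.

## Known limitations

* The SEM is strictly one-factor and Gaussian; no multi-domain latents,
  exposure covariates inside the SEM, or longitudinal layouts.
* The hazard engine has no Makeham term, frailty, or spline baseline.
* OD estimation is anchored on mortality; the interface accepts any
  fitted hazard pair, but non-mortality anchors are not implemented.
* BIC's n and the ROC horizon convention are declared choices; published
  analyses may differ.
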
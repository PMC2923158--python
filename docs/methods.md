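# Methods

## Model

The package fits a shared-random-effects joint model for a Gaussian
longitudinal biomarker and competing-risks failure times (two causes,
hard-wired).  The longitudinal submodel is a linear mixed model

    Y_ij = x_ij' beta1 + W1_i(t_ij) + eps_ij,   eps_ij ~ N(0, sigma2)

with independent measurement errors and a subject-level latent process
W1_i(t) = U0_i + U1_i t (option `re_structure="slope_only"` drops U0).
U0 and U1 are independent zero-mean Gaussians; a correlated pair is
deliberately not modelled (the generator draws them independently, and
the diagonal structure keeps both variance updates conjugate).

The survival submodel attaches, per cause k, a proportional hazard

    lambda_k(t) = lambda_0k(t) exp( z' beta2_k + gamma_k * W1(t) )

to either the subdistribution (Fine–Gray-type, default) or the
cause-specific risk set.  Under the subdistribution kind a subject who
failed from the other cause remains at risk until the administrative
horizon, so Lambda_k feeds the crude cumulative incidence
F_k(t) = 1 − exp(−Lambda_k(t)); under the cause-specific kind every
observed failure or censoring removes the subject.  `at_risk` implements
exactly this contrast.  The two submodels are conditionally independent
given covariates and (U0, U1); `gamma_k` carries the whole association.

### Survival link structure

`survival_link` chooses which part of W1 is scaled by gamma_k in the
hazards: `"intercept_slope"` (full W1, the default for data analysis),
`"slope_only"`, or `"intercept"` (U0 only).  With the piecewise-constant
baseline every cumulative-hazard integral over [a, b] is closed-form,

    lambda_0k * exp(z'beta + g0*U0) * (e^{c b} − e^{c a}) / c,  c = g1*U1,

with the (b − a) limit as c → 0 evaluated through expm1(x)/x to avoid
cancellation (`cumulative_linked_hazard`, verified against adaptive
quadrature at 1e−10 relative error).

### Baseline hazards

The unspecified baselines are piecewise-constant on (by default) 10
intervals per cause with interior cuts at that cause's event-time
quantiles, covering [0, horizon]; intervals are half-open [a, b), so an
event exactly on a boundary belongs to the interval starting there.
Heights carry Gamma(0.01, 0.01) priors.  Because the likelihood is
linear in each height (Poisson/counting-process form), heights have
exact Gamma full conditionals and are Gibbs-updated rather than
Metropolis-updated.

### Coherence

Twin subdistribution models do not constrain F1(t) + F2(t) ≤ 1.
`coherence_check` monitors the sum on a time grid and logs a warning on
violation; nothing is constrained, since constraining would change the
model.

## Sampler

Metropolis-within-Gibbs (`run_mcmc`), fully seeded and deterministic:

* conjugate Gaussian draw for the longitudinal fixed effects; conjugate
  Gamma draws for the error precision and both random-effect precisions;
* per-subject (U0, U1): Metropolis–Hastings with an *independence
  proposal* equal to the exact bivariate-Gaussian full conditional under
  the longitudinal likelihood times the prior.  The acceptance ratio then
  reduces to the survival-likelihood ratio, and is identically one when
  both gammas are zero — so with the association switched off the joint
  posterior factorizes exactly into the separate submodel posteriors;
* group translation moves: the centered parametrization leaves beta_j and
  the mean of the paired random effects nearly confounded (the
  longitudinal likelihood is invariant under beta_j += delta,
  U_i −= w_i delta for design columns constant or proportional to t
  within subject), which makes one-at-a-time updates crawl along that
  ridge and *understate* the marginal posterior spread of the fixed
  effects.  Each iteration therefore samples the shift delta from its
  exact Gaussian conditional under the priors and accepts it through the
  survival-likelihood ratio (a generalized-Gibbs/translation-group move);
* survival coefficients and gammas: random-walk Metropolis, proposal
  scales adapted every 50 iterations toward a 0.25–0.45 acceptance rate
  during burn-in and frozen at `adapt_until` (default: end of burn-in);
* baseline heights: conjugate Gamma, as above.

Initialization (`init_from_separate_fits`) uses a frequentist mixed
model (statsmodels MixedLM, including BLUPs for U) and per-cause
piecewise-exponential Poisson fits with gamma = 0; gammas always start
at 0; failures fall back to neutral values with a logged warning.

Priors: Gaussian(0, 1e4) on all regression coefficients and gammas;
Gamma(0.01, 0.01) on all precisions and heights.  `informative_mode`
centres the longitudinal fixed-effect priors on supplied values with
variance 1 (the replicated-study protocol); everything else stays vague.

Defaults follow the data-analysis protocol (3 chains x 30,000
iterations, burn-in 1,000, thinning 1 — storage is cheap at this scale);
`MCMCConfig.simulation_study()` is the single-chain 10,000-kept-draw
preset and `MCMCConfig.desk()` a scaled-down version for replicated
studies.  Summaries are posterior means, SDs and 2.5/97.5 percentiles
(95% CrI), with an interval-excludes-zero flag.  Convergence uses the
classic potential-scale-reduction factor; values above 1.1 trigger a
warning, not a failure (no universally agreed cutoff).  DIC is computed
conditional on the random effects (subject-level focus, the WinBUGS-style
default): DIC = 2·mean(deviance) − deviance(posterior means), with
pD = mean(deviance) − deviance(posterior means); marginal DIC is out of
scope.

## Synthetic-data generator

`simulate_dataset` emulates a randomized two-arm trial with informative
dropout.  Per subject: X ~ Bernoulli(0.5); U0, U1 ~ N(0, 1) by default;
biomarker at scheduled visits {0,…,7, 14, 28} days with fixed effects
(6.15, −0.25, 0.25, 0) and error variance 0.1; the longitudinal vector is
truncated at the observed event/censoring time (a tied day-of-event
visit is retained).

Failure times use a Fine–Gray-style construction with frailty.  Cause 1
follows the subdistribution

    F1(t; x) = 1 − [1 − p (1 − e^{−t})]^{exp(x beta2 + gamma U0)}

(a unit exponential mixture with mass p = 0.25), so cause 1 occurs with
probability F1(∞) and its time comes from the closed-form inverse of F1.
Cause 2 is exponential with rate lam20 · exp(x beta2 − gamma U0).
Censoring is Exp(0.25), all on the generative scale; times are then
multiplied by `time_scale` into days.

Calibration choices (made once, against the design's own summary
statistics):

* **Frailty entry.**  The default mode puts the frailty in the linear
  predictors through U0 alone (`frailty_mode="intercept"`).  A
  time-varying mode using the full gamma·(U0 + U1 s) inside the cause-1
  subdistribution hazard is implemented
  (`frailty_mode="intercept_slope"`, numerical inversion of the
  cumulative subdistribution hazard), but its integral diverges whenever
  gamma·U1 ≥ 1 — about 16% of subjects at unit slope SD — which forces
  those subjects to cause 1 and pushes the cause-1 fraction far above
  the design's 25%.  The intercept mode reproduces the intended
  25% / 65% / 10% cause-1/cause-2/censored mix, so it is the default, and
  the replicated study fits the matching `"intercept"` survival link.
* **Cause-2 baseline rate.**  With a unit cause-2 rate the mix is
  25/55/19; `lam20 = 4.0` restores 25.4/65.1/9.5 (n = 2·10⁵ check).
* **Time scale.**  `time_scale = 67` maps generative units to days such
  that the visit schedule truncated at dropout yields on average 7.0
  longitudinal observations per subject.
* **No administrative re-censoring.**  Events are not converted to
  censorings at day 28: the event mix is a property of the generative
  process, and the visit schedule already stops at day 28.  The dataset
  horizon is set to cover the largest observed time.

What the generator does *not* emulate: serial correlation or
non-Gaussian tails in the biomarker, time-varying covariates, more than
two causes, covariate-dependent censoring, or a floor/ceiling on the
score.  Passing tests therefore demonstrate correctness of the machinery
and recovery under the stated design, not robustness to those real-data
features.

## Replicated study

`run_simulation_study` runs seeded simulate–fit replicates
(`replicate_seeds` derives collision-free per-replicate seeds below
2³¹) and reports, per tracked parameter, the truth, the bias of the
posterior means and their SD across replicates — the (parameter, truth,
bias (SD)) layout for both association signs.  Replicates whose sampler
aborts are excluded, logged and counted.  Results are a pure function of
(design, n_reps, config, base seed).

## Problem sizes used in the checked-in tests

The test suite keeps single-CPU runtimes modest by scaling problem sizes:
single-replicate recovery uses one n=500 dataset with a 3,000-iteration
chain; the replicated-bias check uses 6 replicates at n=150 with
1,500-iteration chains (bias compared within 2 Monte-Carlo SEs); the
reduction-property check uses n=100; DIC structure preference uses 10
seeds at n=60.  The full-fidelity protocol (100 replicates, n=500,
10,000 kept draws) remains available through
`MCMCConfig.simulation_study()` and the `--preset paper` CLI flag.

## Known limitations

* The cause-2 submodel of a twin-subdistribution fit is mildly
  misspecified with respect to the generator (the true cause-2
  subdistribution given U0 is not exactly proportional-hazards); this
  shows up as a small positive bias (~+0.05–0.1) in gamma1 at n=500,
  comparable to the design's own reported bias scale.
* The subdistribution risk-set extension runs to the horizon without
  censoring weights (IPCW is out of scope); with heavy random censoring
  this over-counts exposure for other-cause failers.  At the ~10%
  censoring of the default design the effect is negligible.
* No marginal (random-effects-integrated) likelihood, no WAIC/LOO, no
  EM/maximum-likelihood path, no left truncation, no interval censoring.
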
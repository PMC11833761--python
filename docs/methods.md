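# Methods

This note documents the models, algorithms and numerical choices behind
`swjoint`, and what its synthetic-data experiments can and cannot show.

## Design and time conventions

A standard complete stepped wedge with `Q` sequences and `J` periods puts
sequence `q` (1-based) on treatment from period `s = q + 1`, so every
cluster has at least one control and one treated period and every cluster is
eventually treated; designs violating either property are rejected. Periods
have unit length (`T_j = j`) and period `j` is the half-open interval
`(j-1, j]`. Treatment for a cluster switches on exactly at its crossover
boundary `t = s - 1`, and the treatment status of a measurement follows the
period it belongs to.

Each subject is measured once per period at the period's right endpoint
`t = j`; there is no baseline (`t = 0`) measurement, consistent with the
period-indicator sum starting at period 1. Where within a period outcomes
are collected is not intrinsic to the model; the period-end convention is
this package's choice and is used consistently by the simulator and both
likelihoods.

## Longitudinal submodel

Nested exchangeable linear mixed model: period fixed effects `beta_j`, a
treatment term (either a constant `delta`, or exposure-time effects
`delta_0..delta_E` indexed by `j - s` with `E` the design's maximum number
of treated periods minus one), a cluster intercept
`alpha ~ N(0, sigma_alpha^2)`, a subject-in-cluster intercept
`phi ~ N(0, sigma_phi^2)` (independent of `alpha`), and residual
`N(0, sigma_eps^2)` noise. The two ICCs are `rho_a = (sa2 + sp2) / total`
within subject and `rho_d = sa2 / total` between subjects.

## Dropout submodel and simulation

Dropout time follows a proportional-hazards model with Weibull baseline
`lambda p t^(p-1)` (exponential is `p = 1`), log hazard ratio `nu` for the
time-varying treatment `X_i(t)`, and shared-random-effect terms
`omega_1 alpha_i + omega_2 phi_ik`. Constraints (`omega_1 = omega_2`, or
either zero) are applied by tying/dropping free coordinates exactly.

Simulation inverts `F(C) = 1 - exp(-H(C)) ` by drawing `u ~ U(0,1)` and
solving `H(C) = -log u` in closed form. Because `X_i(t)` steps from 0 to 1
at the crossover time `tJ`, the cumulative hazard is piecewise and the
inversion branches on `-log u < b` with `b = lambda exp(omega Z) tJ^p`
(dropout before vs after crossover). We solve for the printed `u`-convention
(`F = u` rather than `1 - F = u`); the two are distributionally identical.
Times beyond the study end `T_J` are administratively censored. A property
test verifies `H(C) = -log u` to 1e-10 across randomized parameter draws,
and the null case reproduces the closed-form Weibull law
(Kolmogorov–Smirnov at alpha = 0.01 on 50,000 draws).

The alternative period-level logistic mechanism computes, for every
subject-period cell, `l = nu X_i(j) + omega_1 alpha_i + omega_2 phi_ik`,
z-scores `l` over all cells of the trial (skipped, with a comment in the
code, if the predictor is constant), and draws Bernoulli dropout per period
with probability `logit^{-1}(gamma + z)`; the first success removes that
period's and all later measurements and records the event at the period's
*left* boundary. A subject dropping in period 1 therefore has event time 0;
file validation accepts `time >= 0` and the likelihood floors event times at
1e-8 where a hazard must be evaluated. Under this mechanism both fitted
models are deliberately misspecified (a "neutral" comparison scenario).

Dropout exactly at a measurement time keeps that measurement (the `<=`
censoring rule); dropout is absorbing.

### Random-number discipline

One root seed per simulated trial spawns five named substreams
(`alpha`, `phi`, `eps`, `u`, `bern`) in fixed order, so switching the
dropout mechanism — or disabling dropout — never perturbs the longitudinal
draws, and repetition seeds in the study harness are derived as
`SeedSequence([base_seed, sha256(label), rep])`, making every repetition
independently replayable and parallel execution identical to serial.

## Likelihood

Conditionally on `(alpha, phi)`, a subject contributes a product of normal
densities for its observed measurements (an empty set contributes 1) and a
right-censored survival factor `h(T)^d exp(-H(T))` with the piecewise
`H`. Subjects with no post-censoring measurements still contribute their
survival factor. The cluster marginal likelihood integrates the product of
subject factors over `phi` (per subject) and then over `alpha`; clusters are
independent and their log contributions add.

Both integrals use mean–variance adaptive Gauss–Hermite quadrature,
7 nodes per dimension by default (configurable; at least 3):

- **Subject level.** The conditional posterior of `phi` given `alpha` is
  Gaussian-times-survival-tilt. Adaptation takes the closed-form Gaussian
  mode/precision from the longitudinal part and refines it by Newton steps
  on the full conditional (strictly concave; steps clipped at ±3 and
  iterated to 1e-9, because with extreme association the exponential
  survival term can start the search far from the mode).
- **Cluster level.** A first pass centres on the closed-form mixed-model
  posterior of `alpha` (exact when the association is zero); the weights
  from that pass then update the location and scale to the quadrature-implied
  posterior mean and SD (one mean–variance refresh), and a second pass
  produces the returned value. The refresh happens inside every likelihood
  evaluation — it is deterministic and cheap, so no separate refresh
  schedule is needed.

With zero association the integrand is exactly Gaussian at the adapted
nodes, and the quadrature path reproduces the closed-form nested
exchangeable multivariate-normal log-likelihood to ~1e-12 (tested at 1e-6 on
censored, unbalanced data). At the study's base informative scenario the
7- vs 15-node difference is below 1e-3 total log-likelihood units; under the
extreme associations (`omega = ±log 2`) it grows to a few units — those
scenarios are stress tests, and node count can be raised where they matter.
A 10^6-draw Monte Carlo integration oracle checks the nested integral on a
small instance to within 3 MC SEs.

Variances below a floor of 1e-10 (natural scale) collapse the corresponding
integral to a point mass, keeping integrands finite at the boundary.

## Estimation

Parameters are packed into an unconstrained vector: fixed effects as-is,
`log sigma` for the three standard deviations, `log lambda`, `log p`, `nu`,
and the free association coordinates left by the constraint. L-BFGS-B
maximizes the log-likelihood with box bounds that only keep the log-scale
coordinates away from overflow; convergence is declared on relative
log-likelihood change below 1e-8 (with a 1e-4 projected-gradient target,
500 iterations maximum). Non-convergence is recorded on the result object
and such fits are excluded from performance summaries.

- **LMM.** The fixed effects are profiled out *exactly* by GLS under the
  nested exchangeable covariance (two Woodbury steps; no matrix larger than
  the coefficient matrix is formed), so only the three log-variances are
  optimized, against the closed-form marginal likelihood. The profile
  property means the returned fixed effects solve the GLS normal equations
  at the ML variances to machine precision.
- **Joint model.** Staged starts: the LMM fit seeds the longitudinal block;
  a frailty-free survival fit (moment start `lambda = events / exposure`,
  `p = 1`, `nu = 0`) seeds the hazard block; associations start at 0. The
  joint likelihood is maximized with an analytic score — the gradient of
  the quadrature log-likelihood is the softmax-weighted expectation of the
  conditional score over the node grid, with node locations treated as
  fixed (exact up to the quadrature error; verified against central
  differences at 1e-8 on the constant model). A non-finite likelihood at
  the start triggers one jittered restart before flagging the fit.

Standard errors come from the observed information: a central-difference
Hessian of the log-likelihood (LMM) or of the analytic gradient (joint
model) on the unconstrained scale, inverted via Cholesky — failure to be
positive definite flags the fit and leaves SEs missing. Natural-scale SEs
use the delta method; 95% Wald intervals are formed on the unconstrained
scale and back-transformed, so variance and hazard-parameter intervals
respect positivity. ICC point estimates, SEs and intervals are derived from
the variance block by the delta method.

## Simulation-study harness

Factorial grids: study A (constant effect) crosses
`delta in {0, 5, 25}` x `nu in {-0.2, 0}` x
`omega in {log 0.5, log 0.9, 0, log 2}` (24 scenarios, 6 non-informative);
study B replaces the scalar `delta` with the three exposure-time vectors
`(0,0,0,0)`, `(0, 2.5, 5, 6.25)`, `(0, 12.5, 25, 31.25)`. Five
non-factorial scenarios perturb the informative base
(`delta`-truth 5, `nu = -0.2`, `omega = log 0.9`): 3 clusters per sequence;
3 clusters per sequence with 100 subjects; halved intercept variances
(`1, 27.5` — ICCs 0.416/0.015); doubled (`4, 110` — 0.740/0.026); and the
logistic neutral mechanism. They are appended when
`scenario_grid(..., include_additional=True)` is requested, keeping the
bare grid at its factorial size.

Shared base settings: 4 sequences x 8 clusters x 5 periods x 50 subjects,
`beta_j = 30`, variances `(2, 55, 40)` (ICCs 0.588/0.021), Weibull dropout
with `p = 1`, `lambda = exp(-1.5)`, logistic intercept `gamma = -1.5`.

Performance measures use the standard Monte Carlo formulas — bias, relative
bias (reported as absent, not 0/0, when the truth is zero), empirical SE,
model-based SE (root mean squared reported SE), 95% CI coverage, and
convergence rate — each with its Monte Carlo SE; non-converged fits are
discarded from everything but the convergence rate. The default 1000
repetitions per scenario gives a largest MC error for bias of roughly 2% of
the treatment effect; the bundled tests run 50–500 repetitions, which
widens the MC bands correspondingly.

## What the generator does and does not emulate

The generator produces exactly the data the models describe: Gaussian
outcomes, intercept-only random effects, proportional-hazards dropout tied
to those intercepts (or the logistic alternative). Real trials add
features deliberately absent here — non-Gaussian outcomes, random slopes,
measurement-schedule jitter, open cohorts, interval-censored dropout,
re-entry after dropout, recruitment over time, and competing dropout
causes. Passing tests therefore demonstrate internal correctness
(simulator–likelihood–optimizer consistency and the documented bias
patterns under this DGM), not robustness of the joint model to every real
attrition mechanism; the logistic "neutral" scenario, under which both
fitted models are misspecified, is the one bundled stress of that kind.

## Known limitations

- Baseline hazards are exponential/Weibull only (no Gompertz or splines);
  association is intercept-based (no current-value or slope structures);
  outcomes are Gaussian only.
- ML (not REML) variance components: with few clusters, `sigma_alpha^2` can
  hit zero on individual replicates (the between-cluster information is
  thin), in which case `omega_1` is weakly identified and its SE is large —
  flagged by the information-matrix check rather than hidden.
- Wald intervals for second-order parameters (variances, ICCs) can
  under-cover with small numbers of clusters; the performance tables make
  this visible rather than correcting it.
- The quadrature default of 7 nodes is validated for the study's settings;
  extreme associations warrant more nodes.
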
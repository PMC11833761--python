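# swjoint

Joint longitudinal–survival modelling of informative dropout in
closed-cohort stepped wedge cluster-randomized trials.

## The problem

In a closed-cohort stepped wedge trial, clusters (e.g. clinics) cross from
control to intervention at randomized, staggered times, and the same
subjects are measured once per period throughout. Subjects drop out — and
when the *probability* of dropping out depends on unobserved features of
their outcome trajectory (informative, MNAR attrition), the standard linear
mixed-model analysis of the observed data can be biased.

`swjoint` is for trial statisticians and methodologists who want to

- **simulate** stepped wedge data whose dropout process genuinely shares
  latent structure with the longitudinal outcome,
- **fit** both the conventional nested exchangeable linear mixed model and a
  shared random-effects joint longitudinal–survival model, and
- **compare** them in reproducible Monte Carlo simulation studies (ADEMP
  style: bias, relative bias, empirical/model SE, coverage, convergence).

## The model

Longitudinal submodel (nested exchangeable LMM), for subject *k* in cluster
*i* measured at time *t* in period *j*:

    Y_ijk(t) = sum_j beta_j 1(T_{j-1} < t <= T_j) + delta X_i(t)
               + alpha_i + phi_ik + eps_ijk(t)

with cluster intercept `alpha_i ~ N(0, sigma_alpha^2)`, subject intercept
`phi_ik ~ N(0, sigma_phi^2)`, residual `eps ~ N(0, sigma_eps^2)`, and the
binary treatment path `X_i(t)` determined by the wedge. The constant effect
`delta` may be replaced by exposure-time effects `delta_{j-s}` (time on
treatment). The implied intra-class correlations are

    rho_a = (sigma_alpha^2 + sigma_phi^2) / (sigma_alpha^2 + sigma_phi^2 + sigma_eps^2)   (same subject)
    rho_d =  sigma_alpha^2                / (sigma_alpha^2 + sigma_phi^2 + sigma_eps^2)   (different subjects)

Dropout submodel — a proportional-hazards model sharing the same latent
intercepts through association coefficients (factor loadings) `omega_1,
omega_2`:

    lambda_ik(t) = lambda_0(t) exp(nu X_i(t) + omega_1 alpha_i + omega_2 phi_ik)

with a Weibull baseline `lambda_0(t) = lambda p t^(p-1)` (exponential when
`p = 1`). Setting `omega_1 = omega_2 = 0` recovers ignorable dropout.
Conditionally on `(alpha, phi)` the outcomes and the dropout time are
independent, so the observed-data likelihood is a nested double integral per
cluster, which `swjoint` evaluates by mean–variance adaptive Gauss–Hermite
quadrature and maximizes with an analytic score.

The simulator inverts the piecewise cumulative hazard in closed form (the
treatment covariate switches on at the cluster's crossover time), so every
simulated dropout time satisfies `H(C) = -log u` exactly.

## Worked example

```python
import numpy as np
from swjoint import (
    LongitudinalParams, SurvivalParams, TreatmentEffectSpec,
    build_standard_design, simulate_trial, fit_lmm, fit_joint,
)

design = build_standard_design(
    n_sequences=4, clusters_per_sequence=8, n_periods=5, subjects_per_cluster=50
)
longitudinal = LongitudinalParams(
    period_effects=(30.0,) * 5,
    treatment=TreatmentEffectSpec("constant", 5.0),
    sigma_alpha_sq=2.0, sigma_phi_sq=55.0, sigma_eps_sq=40.0,
)
dropout = SurvivalParams(
    lam=np.exp(-1.5), shape=1.0, nu=-0.2,
    omega1=np.log(0.9), omega2=np.log(0.9),   # informative attrition
)
trial = simulate_trial(design, longitudinal, dropout, seed=7)
print(len(trial.complete), len(trial.observed), int(trial.survival.event.sum()))

lmm = fit_lmm(trial.observed, design)
joint = fit_joint(trial.observed, trial.survival, design)
print(f"LMM    delta = {lmm.estimates['delta']:.3f} (SE {lmm.ses['delta']:.3f})")
print(f"joint  delta = {joint.estimates['delta']:.3f} (SE {joint.ses['delta']:.3f})")
print(f"joint  omega2 = {joint.estimates['omega2']:.3f}, rho_a = {joint.iccs['rho_a'][0]:.3f}")
```

Output:

```
8000 4347 1004
LMM    delta = 4.864 (SE 0.350)
joint  delta = 4.904 (SE 0.346)
joint  omega2 = -0.098, rho_a = 0.608
```

8000 complete measurements shrink to 4347 after dropout censoring (1004 of
1600 subjects drop out before the end of the study). Both models estimate a
treatment effect near the simulated truth of 5; the joint model additionally
recovers the negative subject-level association (`omega_2` close to the
simulated `log 0.9 = -0.105`: subjects with higher outcomes leave more
slowly) and the within-subject correlation `rho_a` near its true 0.588.
Under stronger informative attrition, the mixed model's period effects
drift while the joint model's do not — the pattern the simulation-study
harness (`swjoint.simstudy`, or `swjoint simstudy` on the command line)
quantifies.

## Command line

```sh
swjoint simulate --config scenario.yaml --seed 1 --out data/
swjoint fit --model joint --data data/long.csv --surv data/surv.csv \
        --design scenario.yaml --out fit.csv
swjoint simstudy --study A --reps 1000 --seed 1 --out results/
```

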
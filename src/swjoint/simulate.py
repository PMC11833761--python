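"""Seeded simulation of stepped wedge trial data with informative dropout.

The generator follows the joint-model data-generating mechanism in two steps:

1. simulate complete longitudinal trajectories from the nested exchangeable
   linear mixed model (cluster intercept alpha, subject intercept phi,
   residual noise), one measurement per subject per period;
2. simulate a continuous dropout time per subject from the proportional
   hazards submodel sharing (alpha, phi), by inverting the piecewise
   cumulative hazard that switches at the cluster's crossover time, then
   censor the longitudinal records at the observed time.

An alternative period-level logistic dropout mechanism is also provided.
Randomness is organised as named substreams spawned from one root seed, so
swapping the dropout mechanism never perturbs the longitudinal draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    LogisticDropoutParams,
    LongitudinalParams,
    SurvivalParams,
    TrialDesign,
    exposure_time,
    treatment_indicator,
)

__all__ = [
    "RandomEffectsDraw",
    "SimulatedTrial",
    "draw_random_effects",
    "simulate_complete_longitudinal",
    "invert_dropout_time",
    "simulate_dropout_weibull",
    "simulate_dropout_logistic",
    "apply_dropout",
    "simulate_trial",
]

LONG_COLUMNS = ["cluster_id", "subject_id", "period", "time", "treat", "y"]
SURV_COLUMNS = ["cluster_id", "subject_id", "time", "event", "crossover_time"]

# fixed substream order: changing one mechanism must not shift the others
_STREAMS = ("alpha", "phi", "eps", "u", "bern")


def _substreams(seed) -> dict[str, np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


@dataclass(frozen=True)
class RandomEffectsDraw:
    """One draw of the latent intercepts: alpha per cluster, phi per subject.

    ``alpha`` has shape (n_clusters,); ``phi`` has shape
    (n_clusters, subjects_per_cluster). Cluster ids and subject ids are
    1-based, matching the data files.
    """

    alpha: np.ndarray
    phi: np.ndarray

    def alpha_of(self, cluster: int) -> float:
        return float(self.alpha[cluster - 1])

    def phi_of(self, cluster: int, subject: int) -> float:
        return float(self.phi[cluster - 1, subject - 1])


def draw_random_effects(
    design: TrialDesign,
    sigma_alpha_sq: float,
    sigma_phi_sq: float,
    rng: np.random.Generator,
    phi_rng: np.random.Generator | None = None,
) -> RandomEffectsDraw:
    """Independent normal intercepts alpha_i ~ N(0, sa2), phi_ik ~ N(0, sp2)."""
    if sigma_alpha_sq < 0 or sigma_phi_sq < 0:
        raise ValueError("variances must be nonnegative")
    if phi_rng is None:
        phi_rng = rng
    alpha = rng.normal(0.0, np.sqrt(sigma_alpha_sq), size=design.n_clusters)
    phi = phi_rng.normal(
        0.0,
        np.sqrt(sigma_phi_sq),
        size=(design.n_clusters, design.subjects_per_cluster),
    )
    return RandomEffectsDraw(alpha=alpha, phi=phi)


def _grid(design: TrialDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat (cluster, subject, period) index arrays, all 1-based."""
    n_c, n_s, J = design.n_clusters, design.subjects_per_cluster, design.n_periods
    cluster = np.repeat(np.arange(1, n_c + 1), n_s * J)
    subject = np.tile(np.repeat(np.arange(1, n_s + 1), J), n_c)
    period = np.tile(np.arange(1, J + 1), n_c * n_s)
    return cluster, subject, period


def simulate_complete_longitudinal(
    design: TrialDesign,
    params: LongitudinalParams,
    effects: RandomEffectsDraw,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Complete (no dropout) long-format data: one record per subject-period.

    ``y = beta_j + delta-term * X_i(t) + alpha_i + phi_ik + eps`` with
    ``eps ~ N(0, sigma_eps_sq)``.
    """
    params.validate_for(design)
    cluster, subject, period = _grid(design)
    times = np.asarray(design.measurement_times)[period - 1]

    # per cluster-period: treatment indicator and treatment-effect contribution
    mean_cell = np.empty((design.n_clusters, design.n_periods))
    treat_cell = np.empty((design.n_clusters, design.n_periods), dtype=int)
    for i in design.cluster_ids():
        for j in range(1, design.n_periods + 1):
            e = exposure_time(design, i, j)
            treat_cell[i - 1, j - 1] = 0 if e is None else 1
            mean_cell[i - 1, j - 1] = params.mean(design, i, j)

    m = mean_cell[cluster - 1, period - 1]
    treat = treat_cell[cluster - 1, period - 1]
    eps = rng.normal(0.0, np.sqrt(params.sigma_eps_sq), size=m.shape)
    y = m + effects.alpha[cluster - 1] + effects.phi[cluster - 1, subject - 1] + eps
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "subject_id": subject,
            "period": period,
            "time": times,
            "treat": treat,
            "y": y,
        }
    )


def invert_dropout_time(u, lam, p, nu, omega1, omega2, alpha, phi, tJ):
    """Dropout time solving H(C) = -log(u) under the piecewise hazard.

    The hazard is Weibull ``lam * p * t**(p-1) * exp(wZ)`` before the
    cluster's crossover time ``tJ`` and gains the treatment factor
    ``exp(nu)`` after it, where ``wZ = omega1*alpha + omega2*phi``. With
    ``b = lam * exp(wZ) * tJ**p``:

    - if ``-log u <  b``, dropout happens before crossover:
      ``C = (-log u / (lam * exp(wZ)))**(1/p)``;
    - otherwise it happens after:
      ``C = ((-log u - b + lam*exp(nu + wZ)*tJ**p) / (lam*exp(nu + wZ)))**(1/p)``.

    Vectorised over all arguments.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    lam, p, tJ = (np.asarray(x, dtype=float) for x in (lam, p, tJ))
    if np.any(lam <= 0) or np.any(p <= 0):
        raise ValueError("lam and p must be strictly positive")
    if np.any(tJ <= 0):
        raise ValueError("crossover time tJ must be positive")
    wz = omega1 * np.asarray(alpha, dtype=float) + omega2 * np.asarray(phi, dtype=float)
    neg_log_u = -np.log(u)
    rate0 = lam * np.exp(wz)          # pre-crossover Weibull scale
    rate1 = lam * np.exp(nu + wz)     # post-crossover scale
    b = rate0 * tJ**p
    pre = (neg_log_u / rate0) ** (1.0 / p)
    # clamp the unused branch's numerator at 0 so np.where never sees a
    # negative base; exact wherever the post-crossover branch is selected
    post = ((np.maximum(neg_log_u - b, 0.0) + rate1 * tJ**p) / rate1) ** (1.0 / p)
    out = np.where(neg_log_u < b, pre, post)
    return out if out.ndim else float(out)


def simulate_dropout_weibull(
    design: TrialDesign,
    params: SurvivalParams,
    effects: RandomEffectsDraw,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Continuous dropout times from the shared-random-effects hazard.

    One uniform per subject is inverted through the piecewise cumulative
    hazard (treatment switching at the cluster's crossover time); times past
    the end of the study are administratively censored (event = 0,
    time = T_J).
    """
    n_c, n_s = design.n_clusters, design.subjects_per_cluster
    cluster = np.repeat(np.arange(1, n_c + 1), n_s)
    subject = np.tile(np.arange(1, n_s + 1), n_c)
    tJ = np.array([design.crossover_time(i) for i in design.cluster_ids()])[cluster - 1]
    u = rng.uniform(size=n_c * n_s)
    c = invert_dropout_time(
        u,
        params.lam,
        params.shape,
        params.nu,
        params.omega1,
        params.omega2,
        effects.alpha[cluster - 1],
        effects.phi[cluster - 1, subject - 1],
        tJ,
    )
    end = design.study_end
    event = (c <= end).astype(int)
    time = np.minimum(c, end)
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "subject_id": subject,
            "time": time,
            "event": event,
            "crossover_time": tJ,
        }
    )


def simulate_dropout_logistic(
    design: TrialDesign,
    params: LogisticDropoutParams,
    effects: RandomEffectsDraw,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Period-level Bernoulli dropout with a trial-standardized predictor.

    For each subject-period the linear predictor
    ``l = nu * X_i(period) + w1 * alpha_i + w2 * phi_ik`` is z-scored over
    every subject-period cell of the trial, and the subject drops at the
    first period whose Bernoulli(logit^{-1}(gamma + z)) draw succeeds. The
    event time is the left boundary of that period; survivors are
    administratively censored at T_J.
    """
    n_c, n_s, J = design.n_clusters, design.subjects_per_cluster, design.n_periods
    cluster = np.repeat(np.arange(1, n_c + 1), n_s)
    subject = np.tile(np.arange(1, n_s + 1), n_c)
    tJ = np.array([design.crossover_time(i) for i in design.cluster_ids()])[cluster - 1]

    treat = np.empty((n_c, J))
    for i in design.cluster_ids():
        for j in range(1, J + 1):
            treat[i - 1, j - 1] = treatment_indicator(
                design, i, float(design.measurement_times[j - 1])
            )
    lin = (
        params.nu * treat[cluster - 1, :]
        + params.omega1 * effects.alpha[cluster - 1, None]
        + params.omega2 * effects.phi[cluster - 1, subject - 1, None]
    )  # (n_subjects, J)
    sd = lin.std()
    if sd > 0:
        lin = (lin - lin.mean()) / sd
    # else: all-equal predictor, standardization skipped (degenerate case)
    prob = 1.0 / (1.0 + np.exp(-(params.gamma + lin)))
    draws = rng.uniform(size=prob.shape) < prob
    any_drop = draws.any(axis=1)
    first = np.where(any_drop, draws.argmax(axis=1), J)  # 0-based period index
    boundaries = np.asarray(design.period_boundaries)
    time = np.where(any_drop, boundaries[first], design.study_end)
    event = any_drop.astype(int)
    return pd.DataFrame(
        {
            "cluster_id": cluster,
            "subject_id": subject,
            "time": time,
            "event": event,
            "crossover_time": tJ,
        }
    )


def apply_dropout(complete: pd.DataFrame, survival: pd.DataFrame) -> pd.DataFrame:
    """Censor longitudinal records at the observed time (dropout is absorbing).

    A record is kept iff its measurement time is <= the subject's observed
    time; a measurement taken exactly at the dropout time is kept.
    """
    key = ["cluster_id", "subject_id"]
    obs = survival.set_index(key)["time"]
    idx = pd.MultiIndex.from_frame(complete[key])
    missing = idx.difference(obs.index)
    if len(missing) > 0:
        raise ValueError(f"survival record missing for subject(s) {list(missing[:5])}")
    limit = obs.reindex(idx).to_numpy()
    return complete.loc[complete["time"].to_numpy() <= limit].reset_index(drop=True)


@dataclass(frozen=True)
class SimulatedTrial:
    """Complete + observed longitudinal data, survival data, and the latents."""

    design: TrialDesign
    complete: pd.DataFrame
    observed: pd.DataFrame
    survival: pd.DataFrame
    effects: RandomEffectsDraw


def simulate_trial(
    design: TrialDesign,
    longitudinal: LongitudinalParams,
    dropout: SurvivalParams | LogisticDropoutParams | None,
    seed,
) -> SimulatedTrial:
    """Full trial simulation: latent intercepts, trajectories, dropout, censoring.

    ``dropout`` selects the mechanism (Weibull/exponential hazard or
    period-level logistic); ``None`` means no dropout (all subjects complete,
    survival times administratively censored at T_J). Fully reproducible
    from ``seed``.
    """
    rngs = _substreams(seed)
    effects = draw_random_effects(
        design,
        longitudinal.sigma_alpha_sq,
        longitudinal.sigma_phi_sq,
        rngs["alpha"],
        phi_rng=rngs["phi"],
    )
    complete = simulate_complete_longitudinal(design, longitudinal, effects, rngs["eps"])
    if dropout is None:
        n_c, n_s = design.n_clusters, design.subjects_per_cluster
        cluster = np.repeat(np.arange(1, n_c + 1), n_s)
        survival = pd.DataFrame(
            {
                "cluster_id": cluster,
                "subject_id": np.tile(np.arange(1, n_s + 1), n_c),
                "time": design.study_end,
                "event": 0,
                "crossover_time": np.array(
                    [design.crossover_time(i) for i in design.cluster_ids()]
                )[cluster - 1],
            }
        )
    elif isinstance(dropout, SurvivalParams):
        survival = simulate_dropout_weibull(design, dropout, effects, rngs["u"])
    elif isinstance(dropout, LogisticDropoutParams):
        survival = simulate_dropout_logistic(design, dropout, effects, rngs["bern"])
    else:
        raise TypeError(f"unsupported dropout parameter type {type(dropout)!r}")
    observed = apply_dropout(complete, survival)
    return SimulatedTrial(
        design=design,
        complete=complete,
        observed=observed,
        survival=survival,
        effects=effects,
    )
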
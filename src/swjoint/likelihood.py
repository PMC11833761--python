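"""Observed-data log-likelihood of the joint and linear mixed models.

The marginal likelihood integrates the conditional (given the latent
intercepts) longitudinal and survival contributions over the two nested
random effects:

    L_i = integral over alpha of N(alpha; 0, sa2)
            * prod_k integral over phi of N(phi; 0, sp2)
                * f_Y(y_ik | alpha, phi) * f_T(T_ik, d_ik | alpha, phi) dphi
          dalpha

per cluster i, with subjects k conditionally independent given the effects.
Neither integral is available in closed form once the survival factor is
present, so both are evaluated by mean-variance adaptive Gauss-Hermite
quadrature: the subject-level integral is centred on the Laplace
approximation of the conditional posterior of phi (closed-form Gaussian mode
refined by two Newton steps that add the survival factor), and the
cluster-level integral is centred on the closed-form mixed-model posterior of
alpha and then refreshed once with the mean and variance implied by the
quadrature weights themselves.

With the association coefficients at zero the survival factor drops out of
both integrals and the quadrature reproduces the closed-form nested
exchangeable multivariate-normal likelihood (available here as
:func:`lmm_marginal_loglik`) to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .design import (
    LongitudinalParams,
    SurvivalParams,
    TreatmentEffectSpec,
    TrialDesign,
    exposure_time,
)

__all__ = [
    "VARIANCE_FLOOR",
    "ParameterVector",
    "QuadratureRule",
    "PackedData",
    "linear_predictor",
    "longitudinal_conditional_loglik",
    "hazard",
    "cumulative_hazard",
    "survival_conditional_loglik",
    "survival_only_loglik",
    "cluster_marginal_loglik",
    "total_loglik",
    "lmm_marginal_loglik",
]

# natural-scale floor keeping integrands finite near the variance boundary
VARIANCE_FLOOR = 1e-10

_LOG2PI = float(np.log(2.0 * np.pi))
_SQRT2 = float(np.sqrt(2.0))
_TIME_FLOOR = 1e-8  # guards log(T) and T**(p-1) for events recorded at t=0


# ---------------------------------------------------------------------------
# parameter vector: unconstrained packing of the natural parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """Ordered unconstrained parameterization theta = (theta_Y, theta_t).

    Longitudinal block: period effects, treatment effect(s), log sigma_alpha,
    log sigma_phi, log sigma_eps. Survival block (joint model only):
    log lambda, log shape (Weibull only), nu, and the free association
    coefficients left by ``constraint``. Variances and positive hazard
    parameters live on the log scale so the free vector is unconstrained.
    """

    n_periods: int
    formulation: str = "constant"
    n_deltas: int = 1
    model: str = "joint"  # "lmm" drops the survival block
    family: str = "weibull"
    constraint: str = "none"

    def __post_init__(self) -> None:
        if self.formulation not in ("constant", "exposure"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.model not in ("lmm", "joint"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.family not in ("exponential", "weibull"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.constraint not in ("none", "w1eqw2", "w1zero", "w2zero"):
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.formulation == "constant" and self.n_deltas != 1:
            raise ValueError("constant formulation has exactly one delta")

    @property
    def names(self) -> list[str]:
        out = [f"beta_{j}" for j in range(1, self.n_periods + 1)]
        if self.formulation == "constant":
            out.append("delta")
        else:
            out.extend(f"delta_{e}" for e in range(self.n_deltas))
        out.extend(["log_sigma_alpha", "log_sigma_phi", "log_sigma_eps"])
        if self.model == "joint":
            out.append("log_lambda")
            if self.family == "weibull":
                out.append("log_shape")
            out.append("nu")
            if self.constraint == "none":
                out.extend(["omega1", "omega2"])
            elif self.constraint == "w1eqw2":
                out.append("omega")
            elif self.constraint == "w1zero":
                out.append("omega2")
            else:  # w2zero
                out.append("omega1")
        return out

    @property
    def n_free(self) -> int:
        return len(self.names)

    def pack(
        self, longitudinal: LongitudinalParams, survival: SurvivalParams | None = None
    ) -> np.ndarray:
        """Natural parameter objects -> free unconstrained vector."""
        vals = list(longitudinal.period_effects)
        if self.formulation == "constant":
            vals.append(float(longitudinal.treatment.delta))
        else:
            vals.extend(longitudinal.treatment.delta)
        vals.extend(
            0.5 * np.log(max(v, VARIANCE_FLOOR))
            for v in (
                longitudinal.sigma_alpha_sq,
                longitudinal.sigma_phi_sq,
                longitudinal.sigma_eps_sq,
            )
        )
        if self.model == "joint":
            if survival is None:
                raise ValueError("joint parameterization needs survival parameters")
            vals.append(np.log(survival.lam))
            if self.family == "weibull":
                vals.append(np.log(survival.shape))
            vals.append(survival.nu)
            if self.constraint == "none":
                vals.extend([survival.omega1, survival.omega2])
            elif self.constraint == "w1eqw2":
                vals.append(survival.omega1)
            elif self.constraint == "w1zero":
                vals.append(survival.omega2)
            else:
                vals.append(survival.omega1)
        return np.asarray(vals, dtype=float)

    def unpack(self, theta: np.ndarray) -> tuple[LongitudinalParams, SurvivalParams | None]:
        """Free vector -> natural parameter objects (inverse of :meth:`pack`)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free parameters, got {theta.shape}")
        J = self.n_periods
        pos = J
        beta = tuple(theta[:J])
        if self.formulation == "constant":
            treat = TreatmentEffectSpec("constant", float(theta[pos]))
            pos += 1
        else:
            treat = TreatmentEffectSpec("exposure", tuple(theta[pos : pos + self.n_deltas]))
            pos += self.n_deltas
        sa2, sp2, se2 = np.exp(2.0 * theta[pos : pos + 3])
        pos += 3
        longitudinal = LongitudinalParams(beta, treat, sa2, sp2, se2)
        if self.model == "lmm":
            return longitudinal, None
        lam = float(np.exp(theta[pos]))
        pos += 1
        if self.family == "weibull":
            shape = float(np.exp(theta[pos]))
            pos += 1
        else:
            shape = 1.0
        nu = float(theta[pos])
        pos += 1
        if self.constraint == "none":
            w1, w2 = float(theta[pos]), float(theta[pos + 1])
        elif self.constraint == "w1eqw2":
            w1 = w2 = float(theta[pos])
        elif self.constraint == "w1zero":
            w1, w2 = 0.0, float(theta[pos])
        else:
            w1, w2 = float(theta[pos]), 0.0
        survival = SurvivalParams(
            family=self.family,
            lam=lam,
            shape=shape,
            nu=nu,
            omega1=w1,
            omega2=w2,
            constraint=self.constraint,
        )
        return longitudinal, survival

    @classmethod
    def for_design(
        cls,
        design: TrialDesign,
        formulation: str = "constant",
        model: str = "joint",
        family: str = "weibull",
        constraint: str = "none",
    ) -> "ParameterVector":
        n_deltas = 1 if formulation == "constant" else design.max_exposure() + 1
        return cls(
            n_periods=design.n_periods,
            formulation=formulation,
            n_deltas=n_deltas,
            model=model,
            family=family,
            constraint=constraint,
        )


# ---------------------------------------------------------------------------
# quadrature rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite rule (weight exp(-x^2)) used for both nested integrals."""

    n_nodes: int = 7
    nodes: np.ndarray = field(init=False, repr=False)
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("quadrature needs at least 3 nodes per dimension")
        x, w = np.polynomial.hermite.hermgauss(self.n_nodes)
        object.__setattr__(self, "nodes", x)
        object.__setattr__(self, "weights", w)

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)

    def integrate_gaussian(self, mean: float = 0.0, sd: float = 1.0) -> float:
        """Integral of a normal density (sanity check; exactly 1 analytically)."""
        x = mean + _SQRT2 * sd * self.nodes
        dens = np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        return float(_SQRT2 * sd * np.sum(self.weights * np.exp(self.nodes**2) * dens))


# ---------------------------------------------------------------------------
# conditional building blocks
# ---------------------------------------------------------------------------


def linear_predictor(
    params: LongitudinalParams,
    design: TrialDesign,
    cluster: int,
    period: int,
    t: float,
    alpha: float,
    phi: float,
) -> float:
    """Conditional mean m_ijk(t) + alpha_i + phi_ik of one measurement."""
    if not (0.0 <= t <= design.study_end):
        raise ValueError(f"time {t} outside the study window")
    return params.mean(design, cluster, period) + alpha + phi


def longitudinal_conditional_loglik(
    records: pd.DataFrame,
    params: LongitudinalParams,
    design: TrialDesign,
    alpha: float,
    phi: float,
) -> float:
    """Sum of normal log-densities of a subject's outcomes given the latents.

    An empty record set (every visit censored) contributes 0 — a vacuous
    product over measurements.
    """
    if len(records) == 0:
        return 0.0
    y = records["y"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outcome in longitudinal records")
    se2 = max(params.sigma_eps_sq, VARIANCE_FLOOR)
    mu = np.array(
        [
            linear_predictor(
                params, design, int(r.cluster_id), int(r.period), float(r.time), alpha, phi
            )
            for r in records.itertuples()
        ]
    )
    return float(np.sum(-0.5 * (_LOG2PI + np.log(se2)) - 0.5 * (y - mu) ** 2 / se2))


def hazard(t, tJ, params: SurvivalParams, alpha, phi):
    """Dropout hazard at time t: Weibull baseline times exp(nu X(t) + wZ)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    lam, p = params.lam, params.shape
    wz = params.omega1 * np.asarray(alpha) + params.omega2 * np.asarray(phi)
    x = (t > np.asarray(tJ)).astype(float)
    tt = np.maximum(t, _TIME_FLOOR)
    out = lam * p * tt ** (p - 1.0) * np.exp(params.nu * x + wz)
    return out if out.ndim else float(out)


def cumulative_hazard(t, tJ, params: SurvivalParams, alpha, phi):
    """Piecewise cumulative hazard H(t); treatment switches on at tJ."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    lam, p = params.lam, params.shape
    tJ = np.asarray(tJ, dtype=float)
    wz = params.omega1 * np.asarray(alpha) + params.omega2 * np.asarray(phi)
    base = np.where(
        t <= tJ,
        lam * t**p,
        lam * tJ**p + lam * np.exp(params.nu) * (t**p - tJ**p),
    )
    out = np.exp(wz) * base
    return out if out.ndim else float(out)


def survival_conditional_loglik(
    record, params: SurvivalParams, alpha: float, phi: float
) -> float:
    """Right-censored survival log-density: d*log h(T) - H(T) given the latents."""
    T = float(record["time"])
    d = int(record["event"])
    tJ = float(record["crossover_time"])
    if T < 0 or (T <= 0 and d == 1 and params.shape != 1.0):
        # events exactly at t=0 only make sense for a flat (exponential) hazard
        T = max(T, _TIME_FLOOR)
    if T <= 0:
        raise ValueError("observation time must be positive")
    ll = -cumulative_hazard(T, tJ, params, alpha, phi)
    if d == 1:
        ll += np.log(hazard(T, tJ, params, alpha, phi))
    return float(ll)


def survival_only_loglik(survival: pd.DataFrame, params: SurvivalParams) -> float:
    """Survival log-likelihood at alpha = phi = 0 (no frailty), summed over subjects."""
    T = np.maximum(survival["time"].to_numpy(dtype=float), _TIME_FLOOR)
    d = survival["event"].to_numpy(dtype=int)
    tJ = survival["crossover_time"].to_numpy(dtype=float)
    H = cumulative_hazard(T, tJ, params, 0.0, 0.0)
    lh = np.log(hazard(T, tJ, params, 0.0, 0.0))
    return float(np.sum(d * lh - H))


# ---------------------------------------------------------------------------
# packed data: flat arrays for the vectorized marginal likelihood
# ---------------------------------------------------------------------------


class PackedData:
    """Long + survival data flattened to numpy arrays, subjects indexed 0..n-1.

    The subject roster is the union of subjects appearing in either file, so
    a subject whose every visit was censored still contributes a survival
    factor.
    """

    def __init__(
        self,
        design: TrialDesign,
        long_df: pd.DataFrame,
        surv_df: pd.DataFrame | None = None,
    ) -> None:
        self.design = design
        keys = long_df[["cluster_id", "subject_id"]]
        if surv_df is not None:
            keys = pd.concat([keys, surv_df[["cluster_id", "subject_id"]]])
        roster = keys.drop_duplicates().sort_values(["cluster_id", "subject_id"])
        self.subj_cluster = roster["cluster_id"].to_numpy(dtype=int)
        self.subj_id = roster["subject_id"].to_numpy(dtype=int)
        self.n_subjects = len(roster)
        self.cluster_ids, self.subj_cluster_idx = np.unique(
            self.subj_cluster, return_inverse=True
        )
        self.n_clusters = len(self.cluster_ids)

        lookup = {
            (c, s): i
            for i, (c, s) in enumerate(zip(self.subj_cluster, self.subj_id))
        }
        self.rec_subj = np.array(
            [
                lookup[(c, s)]
                for c, s in zip(long_df["cluster_id"], long_df["subject_id"])
            ],
            dtype=int,
        )
        self.rec_period = long_df["period"].to_numpy(dtype=int)
        self.rec_treat = long_df["treat"].to_numpy(dtype=int)
        self.rec_y = long_df["y"].to_numpy(dtype=float)
        exp_idx = np.array(
            [
                -1 if e is None else e
                for e in (
                    exposure_time(design, int(c), int(j))
                    for c, j in zip(long_df["cluster_id"], self.rec_period)
                )
            ],
            dtype=int,
        )
        self.rec_exposure = exp_idx
        self.n_obs_per_subject = np.bincount(self.rec_subj, minlength=self.n_subjects)

        # per-subject design-column counts, reused by the analytic score
        J = design.n_periods
        n_subj = self.n_subjects
        self.period_counts = np.bincount(
            self.rec_subj * J + (self.rec_period - 1), minlength=n_subj * J
        ).reshape(n_subj, J).astype(float)
        self.treat_counts = np.bincount(
            self.rec_subj, weights=self.rec_treat.astype(float), minlength=n_subj
        ).reshape(n_subj, 1)
        nd = design.max_exposure() + 1
        on = self.rec_exposure >= 0
        self.exposure_counts = np.bincount(
            self.rec_subj[on] * nd + self.rec_exposure[on], minlength=n_subj * nd
        ).reshape(n_subj, nd).astype(float)

        if surv_df is not None:
            sv = surv_df.set_index(["cluster_id", "subject_id"])
            idx = pd.MultiIndex.from_arrays([self.subj_cluster, self.subj_id])
            missing = idx.difference(sv.index)
            if len(missing) > 0:
                raise ValueError(
                    f"survival record missing for subject(s) {list(missing[:5])}"
                )
            sv = sv.reindex(idx)
            self.surv_time = np.maximum(
                sv["time"].to_numpy(dtype=float), _TIME_FLOOR
            )
            self.surv_event = sv["event"].to_numpy(dtype=int)
            self.surv_tJ = sv["crossover_time"].to_numpy(dtype=float)
            self.has_survival = True
        else:
            self.surv_time = self.surv_event = self.surv_tJ = None
            self.has_survival = False

    def fixed_effect_mean(self, params: LongitudinalParams) -> np.ndarray:
        """m_ijk per record for the given fixed effects."""
        beta = np.asarray(params.period_effects)
        m = beta[self.rec_period - 1].copy()
        if params.treatment.formulation == "constant":
            m += float(params.treatment.delta) * self.rec_treat
        else:
            dv = np.asarray(params.treatment.delta)
            on = self.rec_exposure >= 0
            m[on] += dv[self.rec_exposure[on]]
        return m


# ---------------------------------------------------------------------------
# marginal likelihood via nested adaptive quadrature
# ---------------------------------------------------------------------------


def _per_cluster_logliks(
    data: PackedData,
    longitudinal: LongitudinalParams,
    survival: SurvivalParams | None,
    rule: QuadratureRule,
    grad_pv: "ParameterVector | None" = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Log marginal likelihood per cluster (vectorized over all clusters).

    With ``grad_pv`` supplied, also returns the gradient of the *total*
    log-likelihood with respect to that free parameterization. The gradient
    is the quadrature-weighted expectation of the conditional score at the
    adapted nodes (node locations/scales treated as fixed, which is exact up
    to the quadrature error itself).
    """
    sa2 = max(longitudinal.sigma_alpha_sq, VARIANCE_FLOOR)
    sp2 = max(longitudinal.sigma_phi_sq, VARIANCE_FLOOR)
    se2 = max(longitudinal.sigma_eps_sq, VARIANCE_FLOOR)
    n_subj, n_cl = data.n_subjects, data.n_clusters
    cl_idx = data.subj_cluster_idx

    # per-subject longitudinal sufficient stats at these fixed effects
    r = data.rec_y - data.fixed_effect_mean(longitudinal)
    a = data.n_obs_per_subject.astype(float)
    Sr = np.bincount(data.rec_subj, weights=r, minlength=n_subj)
    Sr2 = np.bincount(data.rec_subj, weights=r * r, minlength=n_subj)

    with_surv = survival is not None and data.has_survival
    if with_surv:
        lam, p, nu = survival.lam, survival.shape, survival.nu
        w1, w2 = survival.omega1, survival.omega2
        T, d, tJ = data.surv_time, data.surv_event, data.surv_tJ
        xT = (T > tJ).astype(float)
        H0 = np.where(
            T <= tJ, lam * T**p, lam * tJ**p + lam * np.exp(nu) * (T**p - tJ**p)
        )
        logh0 = np.log(lam * p) + (p - 1.0) * np.log(T) + nu * xT
    else:
        w1 = w2 = 0.0
        H0 = logh0 = d = None

    x, logw = rule.nodes, rule.log_weights
    xsq = x**2

    def _lse_last(g):
        # logsumexp over the last axis without scipy's dispatch overhead
        mx = g.max(axis=-1, keepdims=True)
        return mx[..., 0] + np.log(np.exp(g - mx).sum(axis=-1))

    prec0 = 1.0 / sp2 + a / se2  # conditional precision of phi, longitudinal part
    sp2_deg = longitudinal.sigma_phi_sq < VARIANCE_FLOOR
    sa2_deg = longitudinal.sigma_alpha_sq < VARIANCE_FLOOR

    # cluster blocks are contiguous (roster sorted), so per-cluster sums can
    # use the fast reduceat path instead of scatter-adds
    cluster_starts = np.searchsorted(cl_idx, np.arange(n_cl))

    def conditional_loglik(alpha, phi):
        """log f_Y + log f_T given the latents.

        ``alpha`` and ``phi`` must broadcast together with leading axis
        n_subjects; per-subject arrays are expanded over the trailing axes.
        """
        tail = max(alpha.ndim, phi.ndim) - 1

        def ex(v):
            return v.reshape((n_subj,) + (1,) * tail)

        ap = alpha + phi
        ll = ap * ex(Sr)
        ll -= 0.5 * ex(a) * ap * ap
        ll *= 1.0 / se2
        ll += ex(-0.5 * a * (_LOG2PI + np.log(se2)) - 0.5 * Sr2 / se2)
        if with_surv:
            wz = w1 * alpha + w2 * phi
            ll += ex(d.astype(float)) * wz
            ll += ex(d * logh0)
            ll -= np.exp(wz) * ex(H0)
        return ll

    def inner_logI(alpha_sub, want_moments=False):
        """log integral over phi per (subject, alpha-node); alpha_sub (n_subj, M).

        ``want_moments`` additionally returns the conditional-posterior
        moments of phi under the quadrature weights: E[phi], E[phi^2],
        E[exp(w2 phi)], E[phi exp(w2 phi)] — the pieces the analytic score
        needs.
        """
        if sp2_deg:
            zero = np.zeros_like(alpha_sub)
            logI = conditional_loglik(alpha_sub, zero)
            if want_moments:
                ones = np.ones_like(alpha_sub)
                return logI, (zero, zero, ones, zero)
            return logI
        mode = ((Sr[:, None] - a[:, None] * alpha_sub) / se2) / prec0[:, None]
        curv = np.broadcast_to(prec0[:, None], alpha_sub.shape).copy()
        if with_surv and w2 != 0.0:
            # Newton to convergence on the full (strictly concave) conditional;
            # steps are clipped because the exponential survival term can put
            # the starting point far from the mode when dropout is extreme
            K = H0[:, None] * np.exp(np.clip(w1 * alpha_sub, -700.0, 700.0))
            for _ in range(200):
                e = np.exp(np.clip(w2 * mode, -700.0, 600.0)) * K
                g1 = (
                    -mode / sp2
                    + (Sr[:, None] - a[:, None] * (alpha_sub + mode)) / se2
                    + d[:, None] * w2
                    - w2 * e
                )
                g2 = prec0[:, None] + w2**2 * e
                step = np.clip(g1 / g2, -3.0, 3.0)
                mode = mode + step
                if np.max(np.abs(step)) < 1e-9:
                    break
            curv = prec0[:, None] + w2**2 * np.exp(np.clip(w2 * mode, -700.0, 600.0)) * K
        tau = 1.0 / np.sqrt(curv)
        phi_nodes = mode[..., None] + _SQRT2 * tau[..., None] * x  # (n_subj, M, M2)
        g = conditional_loglik(alpha_sub[..., None], phi_nodes)
        g -= (0.5 / sp2) * phi_nodes * phi_nodes
        g += (logw + xsq) - 0.5 * (_LOG2PI + np.log(sp2))
        mx = g.max(axis=-1, keepdims=True)
        eg = np.exp(g - mx)
        s = eg.sum(axis=-1)
        logI = 0.5 * np.log(2.0) + np.log(tau) + mx[..., 0] + np.log(s)
        if not want_moments:
            return logI
        q = eg / s[..., None]
        E1 = (q * phi_nodes).sum(axis=-1)
        E2 = (q * phi_nodes * phi_nodes).sum(axis=-1)
        if with_surv and w2 != 0.0:
            # computed through the normalized log-weights so large w2*phi
            # nodes with negligible weight cannot overflow
            lq = (g - mx) - np.log(s)[..., None] + w2 * phi_nodes
            ew = np.exp(np.clip(lq, -745.0, 700.0))
            Ew = ew.sum(axis=-1)
            Ewp = (phi_nodes * ew).sum(axis=-1)
        else:
            Ew = np.ones_like(E1)
            Ewp = E1
        return logI, (E1, E2, Ew, Ewp)

    def cluster_G(mu, tau, want_moments=False):
        """Per-cluster log integrand at adapted alpha nodes."""
        alpha_nodes = mu[:, None] + _SQRT2 * tau[:, None] * x  # (n_cl, M)
        res = inner_logI(alpha_nodes[cl_idx], want_moments)
        logI, moments = res if want_moments else (res, None)
        S = np.add.reduceat(logI, cluster_starts, axis=0)
        logprior = -0.5 * (_LOG2PI + np.log(sa2)) - 0.5 * alpha_nodes**2 / sa2
        return alpha_nodes, logprior + S, moments

    def assemble_grad(alpha_nodes, p_out, moments):
        """Total-loglik gradient in grad_pv's free coordinates.

        ``p_out`` (n_cl, M) are the outer softmax weights; the score of each
        free parameter is its conditional derivative averaged over the inner
        (moments) and outer (p_out) quadrature weights.
        """
        E1, E2, Ew, Ewp = moments
        alpha_sub = alpha_nodes[cl_idx]  # (n_subj, M)
        w_km = p_out[cl_idx]
        apE = alpha_sub + E1  # E[alpha + phi | alpha-node]
        J = data.design.n_periods
        out: dict[str, float] = {}

        Sr_jp = np.bincount(
            data.rec_subj * J + (data.rec_period - 1), weights=r, minlength=n_subj * J
        ).reshape(n_subj, J)
        a_jp = data.period_counts
        comp_b = (Sr_jp[:, None, :] - a_jp[:, None, :] * apE[:, :, None]) / se2
        gbeta = np.einsum("km,kmj->j", w_km, comp_b)
        for j in range(J):
            out[f"beta_{j + 1}"] = gbeta[j]

        if grad_pv.formulation == "constant":
            tr = data.rec_treat.astype(float)
            Sr_d = np.bincount(data.rec_subj, weights=r * tr, minlength=n_subj)
            a_d = data.treat_counts[:, 0]
            out["delta"] = float(
                (w_km * (Sr_d[:, None] - a_d[:, None] * apE)).sum() / se2
            )
        else:
            nd = grad_pv.n_deltas
            on = data.rec_exposure >= 0
            Sr_dp = np.bincount(
                data.rec_subj[on] * nd + data.rec_exposure[on],
                weights=r[on],
                minlength=n_subj * nd,
            ).reshape(n_subj, nd)
            comp_d = (Sr_dp[:, None, :] - data.exposure_counts[:, None, :] * apE[:, :, None]) / se2
            gd = np.einsum("km,kmj->j", w_km, comp_d)
            for e in range(nd):
                out[f"delta_{e}"] = gd[e]

        if sa2_deg:
            out["log_sigma_alpha"] = 0.0
        else:
            comp_sa = -1.0 + alpha_nodes**2 / sa2
            out["log_sigma_alpha"] = float((p_out * comp_sa).sum())
        if sp2_deg:
            out["log_sigma_phi"] = 0.0
        else:
            out["log_sigma_phi"] = float((w_km * (-1.0 + E2 / sp2)).sum())
        Eap2 = alpha_sub**2 + 2.0 * alpha_sub * E1 + E2
        comp_se = -a[:, None] + (
            Sr2[:, None] - 2.0 * Sr[:, None] * apE + a[:, None] * Eap2
        ) / se2
        out["log_sigma_eps"] = float((w_km * comp_se).sum())

        if grad_pv.model == "joint":
            logT = np.log(T)
            EW = np.exp(np.clip(w1 * alpha_sub, -700.0, 700.0)) * Ew
            dd = d.astype(float)
            resid_H = dd[:, None] - EW * H0[:, None]
            out["log_lambda"] = float((w_km * resid_H).sum())
            if grad_pv.family == "weibull":
                Hp = lam * p * np.where(
                    T <= tJ,
                    T**p * logT,
                    tJ**p * np.log(tJ)
                    + np.exp(nu) * (T**p * logT - tJ**p * np.log(tJ)),
                )
                out["log_shape"] = float(
                    (
                        w_km
                        * (
                            dd[:, None] * (1.0 + p * logT[:, None])
                            - EW * Hp[:, None]
                        )
                    ).sum()
                )
            Hnu = np.where(T <= tJ, 0.0, lam * np.exp(nu) * (T**p - tJ**p))
            out["nu"] = float(
                (w_km * (dd[:, None] * xT[:, None] - EW * Hnu[:, None])).sum()
            )
            gw1 = float((w_km * alpha_sub * resid_H).sum())
            gw2 = float(
                (
                    w_km
                    * (
                        dd[:, None] * E1
                        - np.exp(np.clip(w1 * alpha_sub, -700.0, 700.0))
                        * Ewp
                        * H0[:, None]
                    )
                ).sum()
            )
            if grad_pv.constraint == "none":
                out["omega1"], out["omega2"] = gw1, gw2
            elif grad_pv.constraint == "w1eqw2":
                out["omega"] = gw1 + gw2
            elif grad_pv.constraint == "w1zero":
                out["omega2"] = gw2
            else:
                out["omega1"] = gw1
        return np.array([out[name] for name in grad_pv.names])

    if sa2_deg:
        if grad_pv is None:
            logI0 = inner_logI(np.zeros((n_subj, 1)))
            return np.add.reduceat(logI0[:, 0], cluster_starts)
        logI0, moments = inner_logI(np.zeros((n_subj, 1)), True)
        ll = np.add.reduceat(logI0[:, 0], cluster_starts)
        grad = assemble_grad(
            np.zeros((n_cl, 1)), np.ones((n_cl, 1)), moments
        )
        return ll, grad

    # pass 1: closed-form mixed-model posterior of alpha (longitudinal info only)
    pos = a > 0
    v = sp2 + se2 / np.where(pos, a, 1.0)  # var of subject mean around alpha
    inv_v = np.where(pos, 1.0 / v, 0.0)
    rbar_over_v = np.where(pos, (Sr / np.where(pos, a, 1.0)) * inv_v, 0.0)
    prec_c = 1.0 / sa2 + np.bincount(cl_idx, weights=inv_v, minlength=n_cl)
    mu_c = np.bincount(cl_idx, weights=rbar_over_v, minlength=n_cl) / prec_c
    tau_c = 1.0 / np.sqrt(prec_c)

    alpha_nodes, G, _ = cluster_G(mu_c, tau_c)
    # mean-variance refresh from the quadrature weights themselves
    logp = logw + xsq + G
    logp = logp - logp.max(axis=1, keepdims=True)
    pwt = np.exp(logp)
    pwt /= pwt.sum(axis=1, keepdims=True)
    mu_new = np.sum(pwt * alpha_nodes, axis=1)
    var_new = np.sum(pwt * alpha_nodes**2, axis=1) - mu_new**2
    ok = var_new > 0
    tau_new = np.where(ok, np.sqrt(np.where(ok, var_new, 1.0)), tau_c)

    alpha_nodes, G, moments = cluster_G(mu_new, tau_new, grad_pv is not None)
    out = 0.5 * np.log(2.0) + np.log(tau_new) + _lse_last(logw + xsq + G)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite cluster marginal log-likelihood")
    if grad_pv is None:
        return out
    logp = logw + xsq + G
    logp = logp - logp.max(axis=1, keepdims=True)
    p_out = np.exp(logp)
    p_out /= p_out.sum(axis=1, keepdims=True)
    return out, assemble_grad(alpha_nodes, p_out, moments)


def cluster_marginal_loglik(
    long_df: pd.DataFrame,
    surv_df: pd.DataFrame | None,
    design: TrialDesign,
    longitudinal: LongitudinalParams,
    survival: SurvivalParams | None = None,
    rule: QuadratureRule | None = None,
) -> float:
    """Marginal log-likelihood of a single cluster's data.

    ``long_df``/``surv_df`` must contain one cluster only; ``survival=None``
    evaluates the mixed-model-only likelihood through the same quadrature
    path.
    """
    rule = rule or QuadratureRule()
    clusters = set(long_df["cluster_id"].unique())
    if surv_df is not None:
        clusters |= set(surv_df["cluster_id"].unique())
    if len(clusters) != 1:
        raise ValueError(f"expected one cluster, found {sorted(clusters)}")
    data = PackedData(design, long_df, surv_df if survival is not None else None)
    return float(_per_cluster_logliks(data, longitudinal, survival, rule).sum())


def total_loglik(
    long_df: pd.DataFrame,
    surv_df: pd.DataFrame | None,
    design: TrialDesign,
    longitudinal: LongitudinalParams,
    survival: SurvivalParams | None = None,
    rule: QuadratureRule | None = None,
) -> float:
    """Total marginal log-likelihood: sum of independent cluster contributions."""
    rule = rule or QuadratureRule()
    data = PackedData(design, long_df, surv_df if survival is not None else None)
    return float(_per_cluster_logliks(data, longitudinal, survival, rule).sum())


# ---------------------------------------------------------------------------
# closed-form nested exchangeable LMM likelihood
# ---------------------------------------------------------------------------


def _lmm_cluster_logliks(
    data: PackedData, longitudinal: LongitudinalParams
) -> np.ndarray:
    """Closed-form marginal normal log-likelihood per cluster.

    Sequential marginalization of phi then alpha gives, per cluster with
    subject visit counts a_k, residual means rbar_k and sums of squares:

        sum_k [ -(a_k/2) log(2 pi se2) - (SS_k - a_k rbar_k^2)/(2 se2)
                + (1/2) log(2 pi se2 / a_k) + log N(rbar_k - alpha; 0, v_k) ]

    with v_k = sp2 + se2/a_k, integrated over alpha ~ N(0, sa2) in closed
    form. Valid for unbalanced data (subjects censored mid-study).
    """
    sp2 = max(longitudinal.sigma_phi_sq, 0.0)
    sa2 = max(longitudinal.sigma_alpha_sq, 0.0)
    se2 = max(longitudinal.sigma_eps_sq, VARIANCE_FLOOR)
    n_subj, n_cl = data.n_subjects, data.n_clusters
    cl_idx = data.subj_cluster_idx

    r = data.rec_y - data.fixed_effect_mean(longitudinal)
    a = data.n_obs_per_subject.astype(float)
    Sr = np.bincount(data.rec_subj, weights=r, minlength=n_subj)
    Sr2 = np.bincount(data.rec_subj, weights=r * r, minlength=n_subj)

    pos = a > 0
    a_safe = np.where(pos, a, 1.0)
    rbar = Sr / a_safe
    v = sp2 + se2 / a_safe
    # alpha-independent part of each subject's integrated-phi factor
    lg0 = np.where(
        pos,
        -0.5 * a * (_LOG2PI + np.log(se2))
        - 0.5 * (Sr2 - a * rbar**2) / se2
        + 0.5 * (_LOG2PI + np.log(se2 / a_safe)),
        0.0,
    )
    inv_v = np.where(pos, 1.0 / v, 0.0)
    # product over subjects of N(rbar_k - alpha; 0, v_k): quadratic in alpha
    P = np.bincount(cl_idx, weights=inv_v, minlength=n_cl)
    m = np.where(P > 0, np.bincount(cl_idx, weights=rbar * inv_v, minlength=n_cl), 0.0)
    m = np.divide(m, P, out=np.zeros_like(m), where=P > 0)
    sum_logn = np.bincount(
        cl_idx,
        weights=np.where(pos, -0.5 * (_LOG2PI + np.log(v)), 0.0),
        minlength=n_cl,
    )
    quad = np.bincount(cl_idx, weights=np.where(pos, rbar**2 * inv_v, 0.0), minlength=n_cl)
    A = sum_logn - 0.5 * (quad - P * m**2)
    out = np.bincount(cl_idx, weights=lg0, minlength=n_cl) + A
    # integrate alpha ~ N(0, sa2) against exp(-P (alpha - m)^2 / 2)
    with_alpha = P > 0
    vtot = sa2 + np.divide(1.0, P, out=np.full_like(P, np.inf), where=with_alpha)
    gauss = np.where(
        with_alpha,
        0.5 * (_LOG2PI - np.log(np.where(with_alpha, P, 1.0)))
        - 0.5 * (_LOG2PI + np.log(vtot))
        - 0.5 * m**2 / vtot,
        0.0,
    )
    return out + gauss


def lmm_marginal_loglik(
    long_df: pd.DataFrame, design: TrialDesign, longitudinal: LongitudinalParams
) -> float:
    """Closed-form marginal log-likelihood of the nested exchangeable LMM."""
    data = PackedData(design, long_df, None)
    return float(_lmm_cluster_logliks(data, longitudinal).sum())
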
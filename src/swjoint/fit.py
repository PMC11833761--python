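"""Maximum likelihood fitting of the mixed and joint models.

Both fits maximize on the unconstrained scale of
:class:`~swjoint.likelihood.ParameterVector` with a quasi-Newton (L-BFGS-B)
optimizer and numerically differenced gradients. Standard errors come from
the observed information (central-difference Hessian of the log-likelihood
at the optimum) and are delta-method mapped to the natural scale; 95% Wald
intervals are built on the unconstrained scale and back-transformed, so
intervals for variances and hazard parameters respect positivity.

Non-convergence is a first-class outcome: the result carries a flag and a
diagnostic message, and downstream performance summaries exclude flagged
fits rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import SurvivalParams, TrialDesign
from .likelihood import (
    PackedData,
    ParameterVector,
    QuadratureRule,
    VARIANCE_FLOOR,
    _lmm_cluster_logliks,
    _per_cluster_logliks,
    survival_only_loglik,
)

__all__ = [
    "FitResult",
    "ICCPair",
    "fit_lmm",
    "fit_joint",
    "observed_information_se",
    "icc_from_variances",
    "wald_ci",
    "numeric_hessian",
]

# convergence: relative loglik change and projected-gradient thresholds
_FTOL = 1e-8
_GTOL = 1e-4
_MAXITER = 500


@dataclass(frozen=True)
class ICCPair:
    """The two intra-class correlations implied by the variance components.

    ``rho_a`` — correlation of two measurements on the *same* individual
    (within-individual ICC); ``rho_d`` — correlation of measurements on
    *different* individuals in the same cluster (between-individuals ICC).
    """

    rho_a: float
    rho_d: float


def icc_from_variances(
    sigma_alpha_sq: float, sigma_phi_sq: float, sigma_eps_sq: float
) -> ICCPair:
    """ICCs of the nested exchangeable model.

    rho_a = (sa2 + sp2) / (sa2 + sp2 + se2), rho_d = sa2 / (sa2 + sp2 + se2).
    """
    for name, v in (
        ("sigma_alpha_sq", sigma_alpha_sq),
        ("sigma_phi_sq", sigma_phi_sq),
        ("sigma_eps_sq", sigma_eps_sq),
    ):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    total = sigma_alpha_sq + sigma_phi_sq + sigma_eps_sq
    if total == 0:
        raise ValueError("ICCs undefined when all variance components are zero")
    return ICCPair(
        rho_a=(sigma_alpha_sq + sigma_phi_sq) / total,
        rho_d=sigma_alpha_sq / total,
    )


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric Wald interval estimate +/- z * SE (on the estimation scale)."""
    if se is None or not np.isfinite(se):
        return (np.nan, np.nan)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fpj = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmj = f(x - ei + ej)
            fmm2 = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpj - fpm - fmj + fmm2) / (4.0 * h[i] * h[j])
    return H


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from one model fit.

    ``params`` maps free-parameter names (unconstrained scale) to rows with
    the natural-scale estimate, SE, and 95% CI. ``iccs`` holds the derived
    ICC point estimates with delta-method SEs and CIs. A fit with
    ``converged=False`` is excluded from performance summaries downstream.
    """

    model: str
    formulation: str
    names: list[str]
    theta_free: np.ndarray
    estimates: dict[str, float]
    ses: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    loglik: float
    converged: bool
    message: str
    n_iter: int
    iccs: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    vcov_free: np.ndarray | None = None
    parameterization: ParameterVector | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat (param, est, se, lo, hi, conv) table, ICCs appended."""
        rows = [
            {
                "param": name,
                "est": self.estimates[name],
                "se": self.ses.get(name, np.nan),
                "lo": self.ci_lower.get(name, np.nan),
                "hi": self.ci_upper.get(name, np.nan),
                "conv": int(self.converged),
            }
            for name in self.names
        ]
        for name, (est, se, lo, hi) in self.iccs.items():
            rows.append(
                {"param": name, "est": est, "se": se, "lo": lo, "hi": hi,
                 "conv": int(self.converged)}
            )
        return pd.DataFrame(rows)


def _natural_name(free_name: str) -> str:
    return {
        "log_sigma_alpha": "sigma_alpha_sq",
        "log_sigma_phi": "sigma_phi_sq",
        "log_sigma_eps": "sigma_eps_sq",
        "log_lambda": "lambda",
        "log_shape": "shape",
    }.get(free_name, free_name)


def _natural_transform(free_name: str, value: float) -> float:
    """Map one free-scale coordinate to its natural-scale parameter."""
    if free_name.startswith("log_sigma"):
        return float(np.exp(np.clip(2.0 * value, -745.0, 709.0)))  # log sigma -> sigma^2
    if free_name in ("log_lambda", "log_shape"):
        return float(np.exp(np.clip(value, -745.0, 709.0)))
    return float(value)


def _build_result(
    pv: ParameterVector,
    theta: np.ndarray,
    loglik: float,
    converged: bool,
    message: str,
    n_iter: int,
    vcov: np.ndarray | None,
) -> FitResult:
    names = pv.names
    nat_names = [_natural_name(n) for n in names]
    estimates, ses, lo, hi = {}, {}, {}, {}
    se_free = (
        np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf)) if vcov is not None else None
    )
    for i, (fn, nn) in enumerate(zip(names, nat_names)):
        est = _natural_transform(fn, theta[i])
        estimates[nn] = est
        if se_free is None or not np.isfinite(se_free[i]):
            ses[nn] = np.nan
            lo[nn], hi[nn] = np.nan, np.nan
            continue
        l_free, h_free = wald_ci(theta[i], se_free[i])
        lo[nn] = _natural_transform(fn, l_free)
        hi[nn] = _natural_transform(fn, h_free)
        # delta method: d(natural)/d(free)
        if fn.startswith("log_sigma"):
            grad = 2.0 * est
        elif fn in ("log_lambda", "log_shape"):
            grad = est
        else:
            grad = 1.0
        ses[nn] = abs(grad) * se_free[i]

    # constrained association coefficients are reported under both natural
    # names so downstream code never needs to know the tying scheme
    if pv.model == "joint" and pv.constraint != "none":
        if pv.constraint == "w1eqw2":
            for dd in (estimates, ses, lo, hi):
                dd["omega1"] = dd["omega2"] = dd["omega"]
        elif pv.constraint == "w1zero":
            estimates["omega1"], ses["omega1"] = 0.0, 0.0
            lo["omega1"] = hi["omega1"] = 0.0
        else:  # w2zero
            estimates["omega2"], ses["omega2"] = 0.0, 0.0
            lo["omega2"] = hi["omega2"] = 0.0

    result = FitResult(
        model=pv.model,
        formulation=pv.formulation,
        names=nat_names,
        theta_free=theta,
        estimates=estimates,
        ses=ses,
        ci_lower=lo,
        ci_upper=hi,
        loglik=loglik,
        converged=converged,
        message=message,
        n_iter=n_iter,
        vcov_free=vcov,
        parameterization=pv,
    )

    # derived ICCs with delta-method SEs from the free-scale covariance
    iv = [names.index(n) for n in ("log_sigma_alpha", "log_sigma_phi", "log_sigma_eps")]
    u = theta[iv]

    def iccs_of(uv: np.ndarray) -> np.ndarray:
        sa2, sp2, se2 = np.exp(2.0 * uv)
        pair = icc_from_variances(sa2, sp2, se2)
        return np.array([pair.rho_a, pair.rho_d])

    vals = iccs_of(u)
    if vcov is not None and np.all(np.isfinite(np.diag(vcov)[iv])):
        step = 1e-6
        Jm = np.empty((2, 3))
        for k in range(3):
            up = u.copy()
            up[k] += step
            um = u.copy()
            um[k] -= step
            Jm[:, k] = (iccs_of(up) - iccs_of(um)) / (2.0 * step)
        sub = vcov[np.ix_(iv, iv)]
        var = np.clip(np.diag(Jm @ sub @ Jm.T), 0.0, np.inf)
        icc_se = np.sqrt(var)
    else:
        icc_se = np.array([np.nan, np.nan])
    for name, v, s in zip(("rho_a", "rho_d"), vals, icc_se):
        l, h = wald_ci(v, s)
        result.iccs[name] = (float(v), float(s), float(l), float(h))
    return result


def observed_information_se(
    negloglik, theta: np.ndarray
) -> tuple[np.ndarray | None, np.ndarray | None, str]:
    """SEs from the inverse observed information at the optimum.

    Returns (vcov, se, message); vcov/se are None when the Hessian of the
    negative log-likelihood is not positive definite.
    """
    H = numeric_hessian(negloglik, np.asarray(theta, dtype=float))
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        return None, None, "observed information not positive definite"
    inv_l = np.linalg.inv(L)
    vcov = inv_l.T @ inv_l
    return vcov, np.sqrt(np.diag(vcov)), "ok"


def _fixed_effect_matrix(data: PackedData, pv: ParameterVector) -> np.ndarray:
    """Record-level design matrix: period dummies then treatment column(s)."""
    n_rec = len(data.rec_y)
    J = pv.n_periods
    X = np.zeros((n_rec, J + pv.n_deltas))
    X[np.arange(n_rec), data.rec_period - 1] = 1.0
    if pv.formulation == "constant":
        X[:, J] = data.rec_treat
    else:
        on = data.rec_exposure >= 0
        X[np.where(on)[0], J + data.rec_exposure[on]] = 1.0
    return X


def _gls_solve(
    data: PackedData, X: np.ndarray, y: np.ndarray,
    sa2: float, sp2: float, se2: float,
) -> np.ndarray:
    """Exact GLS coefficients under the nested exchangeable covariance.

    V^{-1} is applied through two Woodbury steps (subject blocks, then the
    cluster-level rank-one term), so nothing larger than the coefficient
    matrix is ever formed.
    """
    M = np.column_stack([X, y])
    subj = data.rec_subj
    cl_of_rec = data.subj_cluster_idx[subj]
    n_cl = data.n_clusters
    a = data.n_obs_per_subject.astype(float)
    dk = se2 + a * sp2
    # A^{-1} M with A = blockdiag(se2 I + sp2 J_k); A^{-1} 1 = 1/d_k
    m = M.shape[1]
    subj_sums = np.zeros((data.n_subjects, m))
    for c in range(m):
        subj_sums[:, c] = np.bincount(subj, weights=M[:, c], minlength=data.n_subjects)
    AinvM = M / se2 - (sp2 / (se2 * dk[subj]))[:, None] * subj_sums[subj]
    # rank-one cluster update: V = A + sa2 * 1 1'
    S_c = np.bincount(
        data.subj_cluster_idx, weights=a / dk, minlength=n_cl
    )  # 1' A^{-1} 1 per cluster
    colsums = np.zeros((n_cl, m))
    for c in range(m):
        colsums[:, c] = np.bincount(cl_of_rec, weights=AinvM[:, c], minlength=n_cl)
    shrink = sa2 / (1.0 + sa2 * S_c)
    VinvM = AinvM - shrink[cl_of_rec, None] * (1.0 / dk[subj])[:, None] * colsums[cl_of_rec]
    XtVinv = X.T @ VinvM  # (n_fix, n_fix + 1)
    return np.linalg.solve(XtVinv[:, :-1], XtVinv[:, -1])


def _variance_start(data: PackedData, X: np.ndarray) -> np.ndarray:
    """Moment start for (log sigma_alpha, log sigma_phi, log sigma_eps)."""
    coef, *_ = np.linalg.lstsq(X, data.rec_y, rcond=None)
    r = data.rec_y - X @ coef
    subj_mean = np.bincount(data.rec_subj, weights=r, minlength=data.n_subjects) / np.maximum(
        data.n_obs_per_subject, 1
    )
    clus_mean = np.bincount(data.subj_cluster_idx, weights=subj_mean) / np.bincount(
        data.subj_cluster_idx
    )
    sa2 = max(np.var(clus_mean), 1e-3)
    sp2 = max(np.var(subj_mean - clus_mean[data.subj_cluster_idx]), 1e-3)
    se2 = max(np.var(r - subj_mean[data.rec_subj]), 1e-3)
    return 0.5 * np.log([sa2, sp2, se2])


def _free_bounds(pv: ParameterVector) -> list[tuple[float, float]]:
    """Keep log-scale coordinates away from overflow; floor variances."""
    bounds: list[tuple[float, float]] = []
    half_log_floor = 0.5 * np.log(VARIANCE_FLOOR)
    for name in pv.names:
        if name.startswith("log_sigma"):
            bounds.append((half_log_floor, 15.0))
        elif name in ("log_lambda", "log_shape"):
            bounds.append((-20.0, 10.0))
        else:
            bounds.append((-np.inf, np.inf))
    return bounds


def _maximize(negloglik, theta0: np.ndarray, bounds, jac=None) -> optimize.OptimizeResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            jac=jac,
            bounds=bounds,
            options={"ftol": _FTOL, "gtol": _GTOL, "maxiter": _MAXITER, "maxfun": 100000},
        )


def _hessian_from_grad(grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetrized central-difference Hessian built from a gradient function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x[i]))
        e = np.zeros(n)
        e[i] = h
        H[i] = (grad(x + e) - grad(x - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_lmm(
    long_df: pd.DataFrame,
    design: TrialDesign,
    formulation: str = "constant",
    compute_se: bool = True,
) -> FitResult:
    """ML fit of the nested exchangeable linear mixed model.

    The fixed effects are profiled out exactly by GLS at every variance
    iterate, so only the three log-scale variance components are optimized;
    the closed-form marginal normal likelihood means no quadrature is
    needed. Survival data are ignored entirely.
    """
    if long_df["cluster_id"].nunique() < 2:
        raise ValueError("need at least 2 clusters")
    pv = ParameterVector.for_design(design, formulation=formulation, model="lmm")
    data = PackedData(design, long_df, None)
    observed_periods = np.unique(data.rec_period)
    if len(observed_periods) < design.n_periods:
        missing = sorted(set(range(1, design.n_periods + 1)) - set(observed_periods))
        return _build_result(
            pv,
            np.full(pv.n_free, np.nan),
            np.nan,
            False,
            f"singular design: no observations in period(s) {missing}",
            0,
            None,
        )
    X = _fixed_effect_matrix(data, pv)
    n_fix = X.shape[1]

    def profile_negloglik(u):
        sa2, sp2, se2 = np.exp(2.0 * u)
        coef = _gls_solve(data, X, data.rec_y, sa2, sp2, max(se2, VARIANCE_FLOOR))
        longitudinal, _ = pv.unpack(np.concatenate([coef, u]))
        return -float(_lmm_cluster_logliks(data, longitudinal).sum()), coef

    def negloglik_full(theta):
        longitudinal, _ = pv.unpack(theta)
        return -float(_lmm_cluster_logliks(data, longitudinal).sum())

    u0 = _variance_start(data, X)
    res = _maximize(
        lambda u: profile_negloglik(u)[0], u0, _free_bounds(pv)[n_fix:]
    )
    converged = bool(res.success)
    _, coef = profile_negloglik(res.x)
    theta = np.concatenate([coef, res.x])
    vcov = None
    message = res.message if isinstance(res.message, str) else str(res.message)
    if compute_se and converged:
        vcov, _, se_msg = observed_information_se(negloglik_full, theta)
        if vcov is None:
            message += f"; {se_msg}"
    return _build_result(pv, theta, -res.fun, converged, message, res.nit, vcov)


def _survival_start(surv_df: pd.DataFrame, family: str) -> np.ndarray:
    """Moment start for the survival block: lam = events/exposure, p = 1, nu = 0."""
    events = max(surv_df["event"].sum(), 1)
    exposure = max(surv_df["time"].sum(), 1e-8)
    lam0 = events / exposure
    block = [np.log(lam0)]
    if family == "weibull":
        block.append(0.0)  # log shape
    block.append(0.0)  # nu
    return np.asarray(block)


def fit_joint(
    long_df: pd.DataFrame,
    surv_df: pd.DataFrame,
    design: TrialDesign,
    formulation: str = "constant",
    constraint: str = "none",
    family: str = "weibull",
    rule: QuadratureRule | None = None,
    compute_se: bool = True,
) -> FitResult:
    """ML fit of the shared random-effects joint model.

    Two-stage starting values: the LMM fit seeds the longitudinal block, a
    frailty-free survival fit seeds the hazard block, and the association
    coefficients start at zero. The full vector is then maximized through
    the nested adaptive quadrature likelihood. A non-finite likelihood at
    the start triggers one jittered restart before flagging the fit.
    """
    rule = rule or QuadratureRule()
    if surv_df["event"].sum() == 0:
        warnings.warn("no observed dropout events; association is weakly identified")
    pv = ParameterVector.for_design(
        design, formulation=formulation, model="joint", family=family,
        constraint=constraint,
    )
    data = PackedData(design, long_df, surv_df)

    lmm_res = fit_lmm(long_df, design, formulation=formulation, compute_se=False)
    if not lmm_res.converged:
        return _build_result(
            pv,
            np.full(pv.n_free, np.nan),
            np.nan,
            False,
            f"stage-1 LMM fit failed: {lmm_res.message}",
            0,
            None,
        )

    # stage 2: survival-only fit (no random effects, omega = 0)
    surv_block0 = _survival_start(surv_df, family)
    pv_surv_names = ["log_lambda"] + (["log_shape"] if family == "weibull" else []) + ["nu"]

    def surv_negloglik(block):
        lam = float(np.exp(np.clip(block[0], -20, 10)))
        shape = float(np.exp(np.clip(block[1], -20, 10))) if family == "weibull" else 1.0
        nu = float(block[-1])
        sp = SurvivalParams(family=family, lam=lam, shape=shape, nu=nu)
        return -survival_only_loglik(surv_df, sp)

    sres = _maximize(surv_negloglik, surv_block0, [(-20, 10)] * (len(pv_surv_names) - 1) + [(-np.inf, np.inf)])
    surv_block = sres.x if sres.success else surv_block0

    n_assoc = {"none": 2, "w1eqw2": 1, "w1zero": 1, "w2zero": 1}[constraint]
    theta0 = np.concatenate([lmm_res.theta_free, surv_block, np.zeros(n_assoc)])

    def negloglik(theta):
        longitudinal, survival = pv.unpack(theta)
        try:
            return -float(
                _per_cluster_logliks(data, longitudinal, survival, rule).sum()
            )
        except FloatingPointError:
            return np.inf

    def negloglik_and_grad(theta):
        longitudinal, survival = pv.unpack(theta)
        try:
            ll, grad = _per_cluster_logliks(
                data, longitudinal, survival, rule, grad_pv=pv
            )
        except FloatingPointError:
            return np.inf, np.zeros_like(theta)
        f = -float(ll.sum())
        if not np.isfinite(f) or not np.all(np.isfinite(grad)):
            return np.inf, np.zeros_like(theta)
        return f, -grad

    def neg_grad(theta):
        return negloglik_and_grad(theta)[1]

    if not np.isfinite(negloglik(theta0)):
        # one jittered re-seed, then give up
        theta0 = theta0 + 0.01 * np.random.default_rng(0).normal(size=theta0.shape)
        if not np.isfinite(negloglik(theta0)):
            return _build_result(
                pv, theta0, np.nan, False, "non-finite log-likelihood at start", 0, None
            )

    res = _maximize(negloglik_and_grad, theta0, _free_bounds(pv), jac=True)
    converged = bool(res.success) and np.isfinite(res.fun)
    message = res.message if isinstance(res.message, str) else str(res.message)
    vcov = None
    if compute_se and converged:
        H = _hessian_from_grad(neg_grad, res.x)
        try:
            L = np.linalg.cholesky(H)
            inv_l = np.linalg.inv(L)
            vcov = inv_l.T @ inv_l
        except np.linalg.LinAlgError:
            vcov = None
            message += "; observed information not positive definite"
    return _build_result(pv, res.x, -res.fun, converged, message, res.nit, vcov)
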
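"""ADEMP simulation-study harness: scenario grids, repetitions, performance.

Two factorial studies compare the linear mixed model (which assumes
ignorable dropout) with the shared random-effects joint model on data
simulated from the joint data-generating mechanism:

* study A — constant treatment effect delta in {0, 5, 25};
* study B — exposure-time effects with the three delta vectors
  (0,0,0,0), (0, 2.5, 5, 6.25), (0, 12.5, 25, 31.25);

each crossed with the dropout treatment effect nu in {-0.2, 0} and the
association coefficients omega1 = omega2 in {log 0.5, log 0.9, 0, log 2}
(24 scenarios per study; the six with omega = 0 have non-informative
dropout). Non-factorial additions perturb the informative base scenario
(delta = 5, nu = -0.2, omega = log 0.9): fewer clusters, fewer clusters with
more subjects, halved and doubled intercept variances, and the period-level
logistic dropout mechanism under which both fitted models are misspecified.

Performance measures (bias, relative bias, empirical and model-based SE,
coverage, convergence rate) follow the standard Monte Carlo formulas, each
with its Monte Carlo SE; non-converged fits are discarded.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    LogisticDropoutParams,
    LongitudinalParams,
    SurvivalParams,
    TreatmentEffectSpec,
    TrialDesign,
    build_standard_design,
)
from .fit import fit_joint, fit_lmm, icc_from_variances
from .likelihood import QuadratureRule
from .simulate import simulate_trial

__all__ = [
    "ScenarioSpec",
    "scenario_grid",
    "run_repetition",
    "performance_measures",
    "run_study",
]

logger = logging.getLogger("swjoint.simstudy")

# base design and parameter values shared by every scenario
_BASE = dict(
    n_sequences=4,
    clusters_per_sequence=8,
    n_periods=5,
    subjects_per_cluster=50,
    beta=30.0,
    sigma_alpha_sq=2.0,
    sigma_phi_sq=55.0,
    sigma_eps_sq=40.0,
    lam=float(np.exp(-1.5)),
    shape=1.0,
)

_DELTAS_A = (0.0, 5.0, 25.0)
_DELTAS_B = (
    (0.0, 0.0, 0.0, 0.0),
    (0.0, 2.5, 5.0, 6.25),
    (0.0, 12.5, 25.0, 31.25),
)
_NUS = (-0.2, 0.0)
_OMEGAS = (float(np.log(0.5)), float(np.log(0.9)), 0.0, float(np.log(2.0)))


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a simulation study: design, truth, dropout mechanism."""

    label: str
    formulation: str  # constant | exposure
    delta: float | tuple[float, ...]
    nu: float = -0.2
    omega: float = field(default=float(np.log(0.9)))  # omega1 = omega2
    n_sequences: int = 4
    clusters_per_sequence: int = 8
    n_periods: int = 5
    subjects_per_cluster: int = 50
    beta: float = 30.0
    sigma_alpha_sq: float = 2.0
    sigma_phi_sq: float = 55.0
    sigma_eps_sq: float = 40.0
    lam: float = float(np.exp(-1.5))
    shape: float = 1.0
    dropout: str = "weibull"  # weibull | logistic | none
    gamma: float = -1.5  # logistic intercept
    n_reps: int = 1000
    base_seed: int = 0

    def design(self) -> TrialDesign:
        return build_standard_design(
            self.n_sequences,
            self.clusters_per_sequence,
            self.n_periods,
            self.subjects_per_cluster,
        )

    def longitudinal_params(self) -> LongitudinalParams:
        treat = TreatmentEffectSpec(self.formulation, self.delta)
        return LongitudinalParams(
            period_effects=(self.beta,) * self.n_periods,
            treatment=treat,
            sigma_alpha_sq=self.sigma_alpha_sq,
            sigma_phi_sq=self.sigma_phi_sq,
            sigma_eps_sq=self.sigma_eps_sq,
        )

    def dropout_params(self) -> SurvivalParams | LogisticDropoutParams | None:
        if self.dropout == "weibull":
            return SurvivalParams(
                family="weibull",
                lam=self.lam,
                shape=self.shape,
                nu=self.nu,
                omega1=self.omega,
                omega2=self.omega,
            )
        if self.dropout == "logistic":
            return LogisticDropoutParams(
                gamma=self.gamma, nu=self.nu, omega1=self.omega, omega2=self.omega
            )
        if self.dropout == "none":
            return None
        raise ValueError(f"unknown dropout mechanism {self.dropout!r}")

    def truths(self) -> dict[str, float]:
        """True value of every estimand tracked by the study."""
        out = {f"beta_{j}": self.beta for j in range(1, self.n_periods + 1)}
        if self.formulation == "constant":
            out["delta"] = float(self.delta)
        else:
            for e, d in enumerate(self.delta):
                out[f"delta_{e}"] = float(d)
        out["sigma_alpha_sq"] = self.sigma_alpha_sq
        out["sigma_phi_sq"] = self.sigma_phi_sq
        out["sigma_eps_sq"] = self.sigma_eps_sq
        pair = icc_from_variances(
            self.sigma_alpha_sq, self.sigma_phi_sq, self.sigma_eps_sq
        )
        out["rho_a"], out["rho_d"] = pair.rho_a, pair.rho_d
        if self.dropout == "weibull":
            out["lambda"] = self.lam
            out["shape"] = self.shape
            out["nu"] = self.nu
            out["omega1"] = out["omega2"] = self.omega
        return out

    def rep_seed(self, rep_index: int) -> np.random.SeedSequence:
        """Independent, replayable stream per (scenario, repetition)."""
        digest = hashlib.sha256(self.label.encode()).digest()
        scen_key = int.from_bytes(digest[:4], "little")
        return np.random.SeedSequence([self.base_seed, scen_key, rep_index])


def scenario_grid(
    study: str,
    include_additional: bool = False,
    **overrides,
) -> list[ScenarioSpec]:
    """Factorial scenario grid for study A or B, plus optional extras.

    ``include_additional`` appends the five non-factorial scenarios anchored
    at the informative base (delta-truth 5, nu = -0.2, omega = log 0.9):
    3 clusters/sequence; 3 clusters/sequence with 100 subjects; halved
    variances; doubled variances; and the logistic 'neutral' dropout
    mechanism. Keyword overrides (e.g. ``n_reps=10``) apply to every spec.
    """
    if study not in ("A", "B"):
        raise ValueError("study must be 'A' or 'B'")
    formulation = "constant" if study == "A" else "exposure"
    deltas = _DELTAS_A if study == "A" else _DELTAS_B
    specs: list[ScenarioSpec] = []
    for di, delta in enumerate(deltas):
        for nu in _NUS:
            for omega in _OMEGAS:
                label = f"{study}_d{di}_nu{nu:g}_om{omega:.4f}"
                specs.append(
                    ScenarioSpec(
                        label=label,
                        formulation=formulation,
                        delta=delta,
                        nu=nu,
                        omega=omega,
                        **overrides,
                    )
                )
    if include_additional:
        base_delta = 5.0 if study == "A" else (0.0, 2.5, 5.0, 6.25)
        base = ScenarioSpec(
            label=f"{study}_base",
            formulation=formulation,
            delta=base_delta,
            nu=-0.2,
            omega=float(np.log(0.9)),
            **overrides,
        )
        specs.extend(
            [
                replace(base, label=f"{study}_few_clusters", clusters_per_sequence=3),
                replace(
                    base,
                    label=f"{study}_few_clusters_big",
                    clusters_per_sequence=3,
                    subjects_per_cluster=100,
                ),
                replace(
                    base,
                    label=f"{study}_half_var",
                    sigma_alpha_sq=1.0,
                    sigma_phi_sq=27.5,
                ),
                replace(
                    base,
                    label=f"{study}_double_var",
                    sigma_alpha_sq=4.0,
                    sigma_phi_sq=110.0,
                ),
                replace(base, label=f"{study}_logistic_neutral", dropout="logistic"),
            ]
        )
    return specs


def run_repetition(
    spec: ScenarioSpec,
    rep_index: int,
    rule: QuadratureRule | None = None,
    models: tuple[str, ...] = ("lmm", "joint"),
) -> pd.DataFrame:
    """Simulate one trial and fit the requested models.

    Returns one row per model x parameter with the estimate, SE, CI and
    convergence flag; exceptions inside a fit are caught and recorded as a
    non-converged fit rather than raised.
    """
    seed = spec.rep_seed(rep_index)
    trial = simulate_trial(
        spec.design(), spec.longitudinal_params(), spec.dropout_params(), seed
    )
    truths = spec.truths()
    frames = []
    for model in models:
        try:
            if model == "lmm":
                fr = fit_lmm(trial.observed, trial.design, formulation=spec.formulation)
            elif model == "joint":
                fr = fit_joint(
                    trial.observed,
                    trial.survival,
                    trial.design,
                    formulation=spec.formulation,
                    rule=rule,
                )
            else:
                raise ValueError(f"unknown model {model!r}")
            tbl = fr.to_frame()
        except Exception as exc:  # fit failures are data, not crashes
            logger.warning("rep %d %s fit raised: %s", rep_index, model, exc)
            tbl = pd.DataFrame(
                {"param": list(truths), "est": np.nan, "se": np.nan,
                 "lo": np.nan, "hi": np.nan, "conv": 0}
            )
        tbl.insert(0, "model", model)
        tbl.insert(0, "rep", rep_index)
        tbl.insert(0, "scenario", spec.label)
        tbl["truth"] = tbl["param"].map(truths)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def performance_measures(estimates: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Monte Carlo performance summary per (scenario, model, param).

    Expects the long table produced by :func:`run_repetition` (columns
    scenario, model, rep, param, est, se, lo, hi, conv, truth). Computes
    bias, relative bias (only where truth != 0), empirical SE, model-based
    SE, CI coverage and convergence rate, each with its Monte Carlo SE;
    non-converged replicates contribute only to the convergence rate.
    """
    required = {"scenario", "model", "param", "est", "se", "lo", "hi", "conv", "truth"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimate table missing columns {sorted(missing)}")
    rows = []
    for (scenario, model, param), g in estimates.groupby(
        ["scenario", "model", "param"], sort=False
    ):
        n_attempted = len(g)
        conv = g[g["conv"] == 1].dropna(subset=["est"])
        n = len(conv)
        if n == 0:
            raise ValueError(
                f"no converged repetitions for {scenario}/{model}/{param}"
            )
        truth = float(g["truth"].iloc[0])
        est = conv["est"].to_numpy(dtype=float)
        bias = est.mean() - truth
        emp_se = est.std(ddof=1) if n > 1 else 0.0
        bias_mcse = emp_se / np.sqrt(n)
        emp_se_mcse = emp_se / np.sqrt(2.0 * (n - 1)) if n > 1 else np.nan
        se2 = conv["se"].to_numpy(dtype=float) ** 2
        has_se = np.isfinite(se2)
        if has_se.any():
            mod_se = float(np.sqrt(np.mean(se2[has_se])))
            mod_se_mcse = (
                float(np.sqrt(np.var(se2[has_se], ddof=1) / (4.0 * has_se.sum() * mod_se**2)))
                if has_se.sum() > 1 and mod_se > 0
                else np.nan
            )
        else:
            mod_se, mod_se_mcse = np.nan, np.nan
        covered = (conv["lo"] <= truth) & (truth <= conv["hi"])
        has_ci = conv["lo"].notna() & conv["hi"].notna()
        if has_ci.any():
            coverage = float(covered[has_ci].mean())
            cover_mcse = float(np.sqrt(coverage * (1 - coverage) / has_ci.sum()))
        else:
            coverage, cover_mcse = np.nan, np.nan
        conv_rate = n / n_attempted
        rows.append(
            {
                "scenario": scenario,
                "model": model,
                "param": param,
                "truth": truth,
                "n_converged": n,
                "n_attempted": n_attempted,
                "bias": bias,
                "bias_mcse": bias_mcse,
                "rel_bias": bias / truth if truth != 0 else np.nan,
                "rel_bias_mcse": bias_mcse / abs(truth) if truth != 0 else np.nan,
                "emp_se": emp_se,
                "emp_se_mcse": emp_se_mcse,
                "mod_se": mod_se,
                "mod_se_mcse": mod_se_mcse,
                "coverage": coverage,
                "coverage_mcse": cover_mcse,
                "conv_rate": conv_rate,
                "conv_rate_mcse": float(
                    np.sqrt(conv_rate * (1 - conv_rate) / n_attempted)
                ),
            }
        )
    return pd.DataFrame(rows)


def run_study(
    specs: list[ScenarioSpec],
    out_dir: str | Path | None = None,
    rule: QuadratureRule | None = None,
    models: tuple[str, ...] = ("lmm", "joint"),
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every repetition of every scenario; return (estimates, performance).

    Repetitions are independent (seeds derived per scenario x rep), so
    parallel execution with joblib reproduces the serial results exactly.
    """
    all_frames = []
    for spec in specs:
        logger.info("scenario %s: %d repetitions", spec.label, spec.n_reps)
        if n_jobs != 1:
            from joblib import Parallel, delayed

            frames = Parallel(n_jobs=n_jobs)(
                delayed(run_repetition)(spec, r, rule, models)
                for r in range(spec.n_reps)
            )
        else:
            frames = [run_repetition(spec, r, rule, models) for r in range(spec.n_reps)]
        scen = pd.concat(frames, ignore_index=True)
        n_conv = (
            scen[scen["param"] == scen["param"].iloc[0]]
            .groupby("model")["conv"]
            .sum()
            .to_dict()
        )
        logger.info("scenario %s converged: %s", spec.label, n_conv)
        all_frames.append(scen)
    estimates = pd.concat(all_frames, ignore_index=True)
    perf = performance_measures(estimates)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(out / "estimates.csv", index=False)
        perf.to_csv(out / "performance.csv", index=False)
    return estimates, perf
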
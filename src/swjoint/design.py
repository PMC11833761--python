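"""Stepped wedge trial designs and model parameter sets.

A closed-cohort stepped wedge cluster-randomized trial enrols every subject
at baseline and measures them repeatedly in each of ``J`` discrete periods.
Clusters are randomized to intervention *sequences*: sequence ``q`` switches
from control to intervention at the start of period ``s = q + 1`` and stays
treated for the rest of the study (irreversible rollout), so every cluster
contributes at least one control and one treated period.

Time is measured in period units: period ``j`` spans the half-open interval
``(j-1, j]`` and, by convention, each subject is measured once per period at
its right endpoint ``t = j``. A cluster in sequence ``q`` therefore starts
treatment at calendar time ``t = q`` (its *crossover time*).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrialDesign",
    "TreatmentEffectSpec",
    "LongitudinalParams",
    "SurvivalParams",
    "LogisticDropoutParams",
    "build_standard_design",
    "treatment_indicator",
    "exposure_time",
]


@dataclass(frozen=True)
class TrialDesign:
    """Geometry of a closed-cohort stepped wedge trial.

    Parameters
    ----------
    n_periods
        Number of discrete measurement periods ``J``.
    period_boundaries
        Strictly increasing time points ``T_0 < T_1 < ... < T_J`` with
        ``T_0 = 0``; period ``j`` is the interval ``(T_{j-1}, T_j]``.
    sequences
        Crossover period ``s`` (1-based, first *treated* period) for each
        intervention sequence; ``2 <= s <= J`` so every cluster has at least
        one control and one treated period.
    clusters_per_sequence
        Clusters randomized to each sequence.
    subjects_per_cluster
        Cohort size recruited per cluster at baseline.
    measurement_times
        One measurement time per period, lying in ``(T_{j-1}, T_j]``.
    """

    n_periods: int
    period_boundaries: tuple[float, ...]
    sequences: tuple[int, ...]
    clusters_per_sequence: int
    subjects_per_cluster: int
    measurement_times: tuple[float, ...]

    def __post_init__(self) -> None:
        J = self.n_periods
        tb = np.asarray(self.period_boundaries, dtype=float)
        if len(tb) != J + 1:
            raise ValueError(f"expected {J + 1} period boundaries, got {len(tb)}")
        if tb[0] != 0.0:
            raise ValueError("first period boundary T_0 must be 0")
        if not np.all(np.diff(tb) > 0):
            raise ValueError("period boundaries must be strictly increasing")
        mt = np.asarray(self.measurement_times, dtype=float)
        if len(mt) != J:
            raise ValueError(f"expected {J} measurement times, got {len(mt)}")
        for j, t in enumerate(mt, start=1):
            if not (tb[j - 1] < t <= tb[j]):
                raise ValueError(
                    f"measurement time {t} for period {j} outside ({tb[j - 1]}, {tb[j]}]"
                )
        for s in self.sequences:
            if not (2 <= s <= J):
                raise ValueError(
                    f"sequence crossover period {s} outside [2, {J}]: every cluster "
                    "needs at least one control and one treated period"
                )
        if self.clusters_per_sequence < 1 or self.subjects_per_cluster < 1:
            raise ValueError("clusters_per_sequence and subjects_per_cluster must be >= 1")

    # -- derived structure -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_clusters(self) -> int:
        return self.clusters_per_sequence * self.n_sequences

    @property
    def n_subjects(self) -> int:
        return self.n_clusters * self.subjects_per_cluster

    @property
    def study_end(self) -> float:
        return float(self.period_boundaries[-1])

    def cluster_ids(self) -> np.ndarray:
        return np.arange(1, self.n_clusters + 1)

    def sequence_of(self, cluster: int) -> int:
        """1-based sequence index for a 1-based cluster id."""
        if not (1 <= cluster <= self.n_clusters):
            raise KeyError(f"unknown cluster id {cluster}")
        return (cluster - 1) // self.clusters_per_sequence + 1

    def crossover_period(self, cluster: int) -> int:
        """First treated period ``s`` for this cluster's sequence."""
        return self.sequences[self.sequence_of(cluster) - 1]

    def crossover_time(self, cluster: int) -> float:
        """Calendar time at which the cluster starts treatment, ``T_{s-1}``."""
        return float(self.period_boundaries[self.crossover_period(cluster) - 1])

    def period_of_time(self, t: float) -> int | None:
        """Period ``j`` with ``T_{j-1} < t <= T_j``, or None for ``t = T_0``."""
        tb = self.period_boundaries
        if not (tb[0] <= t <= tb[-1]):
            raise ValueError(f"time {t} outside study window [0, {tb[-1]}]")
        if t == tb[0]:
            return None
        j = int(np.searchsorted(tb, t, side="left"))
        return j

    def max_exposure(self) -> int:
        """Largest exposure time ``j - s`` over all sequences and periods."""
        return max(self.n_periods - s for s in self.sequences)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_periods": self.n_periods,
            "period_boundaries": list(self.period_boundaries),
            "sequences": list(self.sequences),
            "clusters_per_sequence": self.clusters_per_sequence,
            "subjects_per_cluster": self.subjects_per_cluster,
            "measurement_times": list(self.measurement_times),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        if "sequences" not in d and "n_sequences" in d:
            return build_standard_design(
                d["n_sequences"],
                d["clusters_per_sequence"],
                d["n_periods"],
                d["subjects_per_cluster"],
            )
        J = int(d["n_periods"])
        return cls(
            n_periods=J,
            period_boundaries=tuple(d.get("period_boundaries", range(J + 1))),
            sequences=tuple(d["sequences"]),
            clusters_per_sequence=int(d["clusters_per_sequence"]),
            subjects_per_cluster=int(d["subjects_per_cluster"]),
            measurement_times=tuple(d.get("measurement_times", range(1, J + 1))),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "TrialDesign":
        return cls.from_dict(json.loads(s))


def build_standard_design(
    n_sequences: int,
    clusters_per_sequence: int,
    n_periods: int,
    subjects_per_cluster: int,
) -> TrialDesign:
    """Standard complete stepped wedge with unit periods.

    Sequence ``q`` (1-based) crosses over at period ``s = q + 1``, i.e.
    treatment starts at calendar time ``t = q``; measurements are taken at
    period ends ``t = 1..J``. The last sequence must still be treated within
    the study, so ``n_sequences <= n_periods - 1``.
    """
    if n_sequences > n_periods - 1:
        raise ValueError(
            f"{n_sequences} sequences do not fit in {n_periods} periods: the last "
            "sequence would never be treated within the study"
        )
    return TrialDesign(
        n_periods=n_periods,
        period_boundaries=tuple(float(j) for j in range(n_periods + 1)),
        sequences=tuple(q + 1 for q in range(1, n_sequences + 1)),
        clusters_per_sequence=clusters_per_sequence,
        subjects_per_cluster=subjects_per_cluster,
        measurement_times=tuple(float(j) for j in range(1, n_periods + 1)),
    )


def treatment_indicator(design: TrialDesign, cluster: int, t: float) -> int:
    """Binary treatment status ``X_i(t)`` of a cluster at calendar time t.

    A time belongs to the period ``(T_{j-1}, T_j]`` it falls in; the cluster
    is treated iff that period is at or after its crossover period. ``t = 0``
    precedes every period and is always control.
    """
    j = design.period_of_time(t)
    if j is None:
        return 0
    return int(j >= design.crossover_period(cluster))


def exposure_time(design: TrialDesign, cluster: int, period: int) -> int | None:
    """Exposure time ``j - s`` (periods on treatment), or None in control periods."""
    if not (1 <= period <= design.n_periods):
        raise ValueError(f"period {period} outside [1, {design.n_periods}]")
    s = design.crossover_period(cluster)
    return period - s if period >= s else None


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Treatment effect on the longitudinal outcome.

    ``constant``: a single immediate effect ``delta`` added in every treated
    period. ``exposure``: a vector ``delta_0..delta_E`` indexed by exposure
    time ``j - s``, allowing the effect to build up (or wane) with time on
    treatment; its length must equal the design's maximum exposure + 1.
    """

    formulation: str
    delta: float | tuple[float, ...]

    def __post_init__(self) -> None:
        if self.formulation not in ("constant", "exposure"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.formulation == "constant":
            if np.ndim(self.delta) != 0:
                raise ValueError("constant formulation takes a scalar delta")
        else:
            if np.ndim(self.delta) != 1:
                raise ValueError("exposure formulation takes a vector of deltas")
            object.__setattr__(self, "delta", tuple(float(d) for d in self.delta))

    def validate_for(self, design: TrialDesign) -> None:
        if self.formulation == "exposure":
            need = design.max_exposure() + 1
            if len(self.delta) != need:
                raise ValueError(
                    f"exposure vector has {len(self.delta)} entries; design needs {need}"
                )

    def effect_at(self, exposure: int | None) -> float:
        """Treatment contribution for a given exposure time (None = control)."""
        if exposure is None:
            return 0.0
        if self.formulation == "constant":
            return float(self.delta)
        return float(self.delta[exposure])


@dataclass(frozen=True)
class LongitudinalParams:
    """Fixed effects and variance components of the linear mixed submodel.

    The noise-free mean at measurement in period j is
    ``m = beta_j + effect_at(exposure) * X_i(t)``; the outcome adds a cluster
    intercept ``alpha ~ N(0, sigma_alpha_sq)``, a subject intercept
    ``phi ~ N(0, sigma_phi_sq)`` and residual noise ``N(0, sigma_eps_sq)``.
    """

    period_effects: tuple[float, ...]
    treatment: TreatmentEffectSpec
    sigma_alpha_sq: float
    sigma_phi_sq: float
    sigma_eps_sq: float

    def __post_init__(self) -> None:
        for name in ("sigma_alpha_sq", "sigma_phi_sq", "sigma_eps_sq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        object.__setattr__(
            self, "period_effects", tuple(float(b) for b in self.period_effects)
        )

    def validate_for(self, design: TrialDesign) -> None:
        if len(self.period_effects) != design.n_periods:
            raise ValueError(
                f"{len(self.period_effects)} period effects for {design.n_periods} periods"
            )
        self.treatment.validate_for(design)

    def mean(self, design: TrialDesign, cluster: int, period: int) -> float:
        """Fixed-effect mean m for a cluster-period cell."""
        return float(self.period_effects[period - 1]) + self.treatment.effect_at(
            exposure_time(design, cluster, period)
        )


_CONSTRAINTS = ("none", "w1eqw2", "w1zero", "w2zero")


@dataclass(frozen=True)
class SurvivalParams:
    """Proportional-hazards dropout submodel with shared random effects.

    Hazard ``lambda_ik(t) = lam0(t) * exp(nu * X_i(t) + w1*alpha_i + w2*phi_ik)``
    with a Weibull baseline ``lam0(t) = lam * p * t**(p-1)`` (exponential is
    the ``p = 1`` special case). ``nu`` is the log hazard ratio of treatment
    on dropout; ``w1``/``w2`` are the association coefficients (factor
    loadings) tying dropout to the cluster and subject intercepts of the
    longitudinal submodel. ``constraint`` ties or zeroes them.
    """

    family: str = "weibull"
    lam: float = 1.0
    shape: float = 1.0
    nu: float = 0.0
    omega1: float = 0.0
    omega2: float = 0.0
    constraint: str = "none"

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline family {self.family!r}")
        if self.lam <= 0 or self.shape <= 0:
            raise ValueError("lam and shape must be strictly positive")
        if self.family == "exponential" and self.shape != 1.0:
            raise ValueError("exponential baseline requires shape = 1")
        if self.constraint not in _CONSTRAINTS:
            raise ValueError(f"unknown constraint {self.constraint!r}")
        if self.constraint == "w1eqw2" and self.omega1 != self.omega2:
            raise ValueError("constraint w1eqw2 requires omega1 == omega2")
        if self.constraint == "w1zero" and self.omega1 != 0.0:
            raise ValueError("constraint w1zero requires omega1 == 0")
        if self.constraint == "w2zero" and self.omega2 != 0.0:
            raise ValueError("constraint w2zero requires omega2 == 0")


@dataclass(frozen=True)
class LogisticDropoutParams:
    """Period-level logistic dropout model (alternative, 'neutral' mechanism).

    P(dropout in period j) = logit^{-1}(gamma + z) where z is the
    trial-standardized linear predictor nu*X_i + w1*alpha_i + w2*phi_ik.
    """

    gamma: float
    nu: float = 0.0
    omega1: float = 0.0
    omega2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma", "nu", "omega1", "omega2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
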
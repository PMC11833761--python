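import numpy as np
import pytest

from swjoint import (
    LongitudinalParams,
    SurvivalParams,
    TreatmentEffectSpec,
    build_standard_design,
    simulate_trial,
)

BASE_BETA = (30.0, 30.0, 30.0, 30.0, 30.0)
BASE_VARIANCES = dict(sigma_alpha_sq=2.0, sigma_phi_sq=55.0, sigma_eps_sq=40.0)
BASE_LAM = float(np.exp(-1.5))


@pytest.fixture(scope="session")
def base_design():
    """The 32-cluster, 4-sequence, 5-period, 50-subject study design."""
    return build_standard_design(4, 8, 5, 50)


@pytest.fixture(scope="session")
def small_design():
    """A light 8-cluster version of the same wedge for fast fitting tests."""
    return build_standard_design(4, 2, 5, 12)


@pytest.fixture(scope="session")
def base_longitudinal():
    return LongitudinalParams(
        period_effects=BASE_BETA,
        treatment=TreatmentEffectSpec("constant", 5.0),
        **BASE_VARIANCES,
    )


@pytest.fixture(scope="session")
def informative_dropout():
    """Weibull dropout with treatment effect and shared-intercept association."""
    return SurvivalParams(
        family="weibull",
        lam=BASE_LAM,
        shape=1.0,
        nu=-0.2,
        omega1=float(np.log(0.9)),
        omega2=float(np.log(0.9)),
    )


@pytest.fixture(scope="session")
def base_trial(base_design, base_longitudinal, informative_dropout):
    """One simulated trial from the informative base scenario."""
    return simulate_trial(base_design, base_longitudinal, informative_dropout, 20240101)


@pytest.fixture(scope="session")
def small_trial(small_design, base_longitudinal, informative_dropout):
    return simulate_trial(small_design, base_longitudinal, informative_dropout, 555)
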
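import numpy as np
import pytest

from mcots.mcots_model import MCoTSParams
from mcots.simulate import (
    CohortConfig,
    GenerativeParams,
    OutcomeParams,
    recovery_config,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def test_params() -> MCoTSParams:
    """Arbitrary admissible MCoTS settings used throughout the suite."""
    return MCoTSParams(
        a1=np.sqrt(0.35), c1=np.sqrt(0.05), e1=np.sqrt(0.60),
        a2=np.sqrt(0.6), c2=np.sqrt(0.1), e2=np.sqrt(0.3),
        rA=0.5, m=0.1,
    )


def generative_from(params: MCoTSParams, outcome: str = "adhd_age8",
                    **overrides) -> GenerativeParams:
    op = OutcomeParams(a2=params.a2, c2=params.c2, e2=params.e2,
                       rA=overrides.pop("rA", params.rA),
                       m=overrides.pop("m", params.m))
    return GenerativeParams(
        a1=params.a1, c1=params.c1, e1=params.e1,
        outcomes={outcome: op},
        beta_age=0.0, beta_parity=0.0, beta_birth_year=0.0, beta_sex=0.0,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort(test_params):
    """One mixed-relationship cohort reused by fitting tests."""
    gp = generative_from(test_params)
    return simulate_cohort(recovery_config(1500, seed=42), gp,
                           outcomes=["adhd_age8"])


@pytest.fixture(scope="session")
def demo_cohort():
    """Tiny cohort with demographics, covariate effects and missingness."""
    cfg = CohortConfig(
        n_families=400,
        missingness={"adhd_adult": 0.2, "adhd_age8": 0.2},
        seed=7,
    )
    return simulate_cohort(cfg, GenerativeParams(), outcomes=["adhd_age8"])
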
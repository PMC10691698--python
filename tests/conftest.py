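import numpy as np
import pytest

from edcrowd import (ModelParams, WeeklyArrivalProfile, calibrate_profile,
                     generate_visit_log)
from edcrowd.params import DAY_GROUPS, reference_params


@pytest.fixture(scope="session")
def ref_params() -> ModelParams:
    """Exit rates and noise magnitudes of the reference ED."""
    return reference_params()


@pytest.fixture(scope="session")
def flat_profile() -> WeeklyArrivalProfile:
    return WeeklyArrivalProfile(np.full(168, 14.0))


def const_params(beta: float = 0.25, sigma1: float = 1.0,
                 sigma2: float = 0.0) -> ModelParams:
    return ModelParams({g: beta for g in DAY_GROUPS},
                       sigma1=sigma1, sigma2=sigma2)


@pytest.fixture(scope="session")
def calibrated_profile(ref_params) -> WeeklyArrivalProfile:
    """The reference-study weekly arrival profile (calibrated once)."""
    return calibrate_profile(ref_params, seed=0)


@pytest.fixture(scope="session")
def study_log(calibrated_profile, ref_params):
    """A 100-week synthetic study at the reference parameters."""
    return generate_visit_log(calibrated_profile, ref_params,
                              n_weeks=100, seed=7)
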
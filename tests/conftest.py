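import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import locmem as lm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: group-level generating parameters of the reference low-risk group:
#: guess rate 0.31, localization SD 17.9 degrees.
E3E3_P_GUESS = 0.31
E3E3_SD_DEG = 17.90


@pytest.fixture(scope="session")
def e3e3_params():
    kappa = lm.kappa_sd_convert(E3E3_SD_DEG, "sd_to_kappa").kappa
    return lm.MixtureParams(kappa=kappa, p_guess=E3E3_P_GUESS)


@pytest.fixture(scope="session")
def model2_errors_20k(e3e3_params):
    """20,000 signed errors from the two-component mixture at the reference
    group-level parameters."""
    return lm.sample_mixture_errors(e3e3_params, 20_000, rng=12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced null-effect cohort for smoke tests (2 x 10 subjects)."""
    import dataclasses

    spec = lm.null_cohort_spec(master_seed=77)
    g1 = dataclasses.replace(spec.groups[0], n=10)
    g2 = dataclasses.replace(spec.groups[1], n=10)
    spec = dataclasses.replace(spec, groups=(g1, g2))
    return lm.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size two-group cohort at reference demographics."""
    return lm.generate_cohort(lm.default_cohort_spec(master_seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
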
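import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from accelseg.synth import SimulationConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def short_cfg():
    """Calibrated defaults at a short duration (10 min → 10 segments)."""
    return SimulationConfig(seed=7, duration_s=600.0)


@pytest.fixture(scope="session")
def null_battery_pvalues():
    """Raw p-values of the MWU/KS/BWS battery over 2000 null 5-vs-10 draws.

    Both groups come from the same normal distribution, so every rejection
    is a type-I error. Shared by the per-test level checks and the
    family-wise error check.
    """
    from accelseg import stats as st

    gen = np.random.default_rng(987654321)
    n_sim = 2000
    out = np.empty((n_sim, 3))
    for k in range(n_sim):
        a = gen.standard_normal(5)
        b = gen.standard_normal(10)
        out[k, 0] = st.mann_whitney_u(a, b).p
        out[k, 1] = st.kolmogorov_smirnov(a, b).p
        out[k, 2] = st.bws_test(a, b, method="exact_permutation").p
    return out
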
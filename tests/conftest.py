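import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_roi_cohort():
    """Tiny two-group coupled-dynamics cohort shared across group-level tests."""
    from flowconn.synthetic import default_coupling_spec, gen_var_cohort

    base = default_coupling_spec(n_samples=3000)
    return gen_var_cohort(4, base_spec=base, group_gain=1.8, seed=7)


@pytest.fixture(scope="session")
def small_flow_matrices(small_roi_cohort):
    from flowconn.flow import ifr_matrix

    mats = [ifr_matrix(ts) for ts in small_roi_cohort.participants]
    by_group = {}
    for fm, lab in zip(mats, small_roi_cohort.group_labels):
        by_group.setdefault(lab, []).append(fm)
    return by_group
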
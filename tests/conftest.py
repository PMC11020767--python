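import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abtau import HealthReference, InflammationField, default_params, integrate_ode

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    return HealthReference()


@pytest.fixture(scope="session")
def params(ref):
    return default_params(ref)


@pytest.fixture(scope="session")
def scenario_endpoints(params, ref):
    """3650-day endpoints of the four published well-mixed scenarios."""
    out = {}
    for mults in [(0.0, 0.0), (1.0, 1.0), (1.5, 0.5), (0.5, 1.5)]:
        field = InflammationField.uniform(
            mults[0] * 1.85e-6, mults[1] * 4.13e-10, K=100.0, gamma=1.0
        )
        traj = integrate_ode(params, ref, field, 3650.0, sample_interval=50.0)
        out[mults] = traj
    return out


@pytest.fixture(scope="session")
def slow_ramp_runs(params, ref):
    """Untreated and treated (t0=2000, 2300) slow-ramp trajectories."""
    from abtau.treatment import DrugRegimen, slow_ramp_field

    field = slow_ramp_field()
    runs = {"untreated": integrate_ode(params, ref, field, 3650.0)}
    for t0 in (2000.0, 2300.0):
        runs[t0] = integrate_ode(
            params, ref, field, 3650.0, drug=DrugRegimen(t0=t0)
        )
    return runs


def rel_err(a, b):
    return np.abs(np.asarray(a) - np.asarray(b)) / np.abs(np.asarray(b))
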
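import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One 45-patient synthetic trial under the default study conditions."""
    from tcrbm.synthetic import SimulationConfig, simulate_trial

    return simulate_trial(SimulationConfig(seed=11))


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Independent Cox partial log-likelihood (Breslow form; no ties in use)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_mle(times, events, x, lo=-10.0, hi=10.0) -> float:
    """Brute-force 1-D maximizer of the Cox partial likelihood."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
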
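import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from insom.model import ModelParams, entrain, integrate
from insom.scenarios import build_sleep_schedule
from insom.units import MelanopicIrradianceSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def square_day_series(days: int, level: float, on: float = 6.0,
                      off: float = 22.0, dt: float = 60.0,
                      **kw) -> MelanopicIrradianceSeries:
    """Rectangular photoperiod: ``level`` W m⁻² between ``on`` and ``off``."""
    t = np.arange(0.0, days * 86400.0, dt)
    h = (t / 3600.0) % 24.0
    return MelanopicIrradianceSeries(
        t, np.where((h >= on) & (h < off), level, 0.0), **kw
    )


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def scheduled():
    return build_sleep_schedule("scheduled")


@pytest.fixture(scope="session")
def disrupted():
    return build_sleep_schedule("disrupted")


@pytest.fixture(scope="session")
def entrained_state(params, scheduled):
    """State after 7 entrainment days under a 16:8 0.5 W m⁻² photoperiod."""
    return entrain(scheduled, params, days=7,
                   exposure=square_day_series(1, 0.5))


@pytest.fixture(scope="session")
def week_trajectory(params, scheduled, entrained_state):
    """Entrained 7-day forced-mode run, 16:8 photoperiod at 0.5 W m⁻²."""
    return integrate(square_day_series(7, 0.5), scheduled, params,
                     initial_state=entrained_state)
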
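import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from extravakit import (
    ARM_CONTRALATERAL,
    ARM_INJECTION,
    AdministrationSession,
    DoseRateCurve,
    SphereDoseTable,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def dose_table():
    """Sphere-model factors spanning the depot masses seen clinically."""
    return SphereDoseTable(
        masses_g=np.array([1.0, 20.0, 50.0]),
        dose_factors_mgy_per_mbq=np.array([268.0, 22.4, 9.4]),
    )


def make_step_session(
    peak=1000.0,
    plateau=100.0,
    contralateral=80.0,
    t_peak=60.0,
    duration=700.0,
    a_in=250.0,
):
    """Noiseless piecewise-constant session: baseline 0, a single peak
    sample, then flat plateaus on both arms.  The simplest curve on which
    the metric identities can be checked against hand arithmetic."""
    t = np.arange(0.0, duration)
    inj = np.zeros_like(t)
    inj[t > t_peak] = plateau
    inj[int(t_peak)] = peak
    con = np.zeros_like(t)
    con[t > t_peak] = contralateral
    return AdministrationSession(
        patient_id="step",
        injected_activity_mbq=a_in,
        injection_curve=DoseRateCurve(t, inj, ARM_INJECTION),
        contralateral_curve=DoseRateCurve(t, con, ARM_CONTRALATERAL),
    )


@pytest.fixture
def step_session():
    return make_step_session()
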
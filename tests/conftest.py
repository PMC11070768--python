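import numpy as np
import pytest

from hrdrift import (
    ActivitySegment,
    HrBounds,
    ModelParameters,
    SessionSeries,
    SimulationConfig,
    SubjectProfile,
    simulate_session,
)


@pytest.fixture
def subject() -> SubjectProfile:
    return SubjectProfile(age=28, vo2max=50.0, pa_rating=3)


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def bounds() -> HrBounds:
    return HrBounds(hr_rest=60.0, hr_max=190.0)


@pytest.fixture
def bte_session():
    return simulate_session(SimulationConfig(protocol="BTE", seed=11))


@pytest.fixture
def max_session():
    return simulate_session(SimulationConfig(protocol="MAX", seed=11))


@pytest.fixture
def flat_series() -> SessionSeries:
    """Ten minutes at a constant 100 bpm / 10 mL/kg/min, all rest."""
    n = 600
    t = np.arange(n, dtype=float)
    return SessionSeries(
        time=t,
        hr=np.full(n, 100.0),
        vo2=np.full(n, 10.0),
        segments=(ActivitySegment(0.0, float(n), "rest"),),
    )
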
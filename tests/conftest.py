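import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vffr import (
    AorticWaveformParams,
    CMVParameters,
    IntramyocardialParams,
    LesionCharacteristic,
    generate_cohort,
    synthesize_aortic_pressure,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pulsatile_pa():
    """A representative pulsatile aortic trace (72 bpm, 125/75 mmHg)."""
    return synthesize_aortic_pressure(
        AorticWaveformParams(72, 125, 75, 0.35), dt=1e-3, n_cycles=1
    )


@pytest.fixture(scope="session")
def moderate_lesion():
    return LesionCharacteristic(4.0, 2.0)


@pytest.fixture(scope="session")
def typical_cmv():
    return CMVParameters(
        R=28.0,
        C=0.005,
        Z_c=1.0,
        pim=IntramyocardialParams(
            amplitude=25.0, t_gen=0.10, t_plateau=0.15, tau_decay=0.05
        ),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default 73-case seeded study cohort (shared across tests)."""
    return generate_cohort(n=73, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
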
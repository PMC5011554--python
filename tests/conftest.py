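import datetime as dt

import numpy as np
import pytest

from legwork.cohort import Participant, Regimen, simulate_bout
from legwork.device import (
    HIGH_SENSITIVITY,
    LOW_SENSITIVITY,
    PowerTrace,
    simulate_temperature,
)

SEED = 17  # package default master seed


@pytest.fixture(scope="session")
def mean_participant() -> Participant:
    return Participant(id="demo")


@pytest.fixture(scope="session")
def mict_regimen() -> Regimen:
    return Regimen(control="hold_hr", target=100.0, duration=30.0)


@pytest.fixture(scope="session")
def vigorous_bout(mean_participant):
    """Seeded HR-130 high-sensitivity bout with planted onset at 7 min."""
    return simulate_bout(
        mean_participant,
        Regimen(control="hold_hr", target=130.0, duration=30.0),
        HIGH_SENSITIVITY,
        clock_time=dt.time(14, 0),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def fatigue_free_bout(mean_participant, mict_regimen):
    """Seeded 30-min moderate bout: onset (31 min) beyond the duration."""
    return simulate_bout(
        mean_participant, mict_regimen, LOW_SENSITIVITY,
        clock_time=dt.time(14, 0), seed=SEED,
    )


def constant_power_trace(level: float, minutes: int, params, noise_sd=0.0, seed=0):
    times = np.arange(minutes + 1, dtype=float)
    power = PowerTrace(times=times, power=np.full(minutes + 1, level))
    rng = np.random.default_rng(seed) if noise_sd else None
    return simulate_temperature(power, params, noise_sd=noise_sd, rng=rng)
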
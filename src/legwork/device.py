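"""First-order thermal model of the leg-training device's resistance unit.

The training device dissipates the user's mechanical work as heat in a
friction/resistance unit, and a wireless sensor reports the temperature rise
above the session-start baseline (written Δt°, °C) once per minute.  Because
the heating rate tracks the instantaneous work rate while the unit loses heat
to the surroundings, Δt° obeys Newton-type heating/cooling dynamics

    dΔ/dτ = α · P(τ) − λ · Δ(τ),        Δ(0) = 0,

with P the latent leg work output (LWO) in work-units per minute (the
mean-participant moderate work rate defines 1.0 work-unit/min), α the sensor
gain in °C per work-unit, and λ the per-minute cooling rate.  The sensor can
be mounted in two positions:

* ``high`` sensitivity — strong coupling, fast cooling (λ on the order of
  0.4/min), so Δt° plateaus within a bout at the steady state α·P/λ and the
  plateau level resolves differences in work rate between participants.
* ``low`` sensitivity — weak coupling, very slow cooling (λ·30 min ≪ 1), so
  Δt° rises quasi-linearly for at least 30 minutes and the value reached in a
  bout integrates the work done — the basis for exercise "doses".

Default calibrations anchor the model to the study-scale quantities: a
unit-power participant plateaus at 34.2 °C in high mode and accumulates
8.1 °C in a 30-minute low-mode bout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Mode",
    "DeviceParams",
    "SensorTrace",
    "PowerTrace",
    "HIGH_SENSITIVITY",
    "LOW_SENSITIVITY",
    "simulate_temperature",
    "steady_state_delta",
    "estimate_power",
    "GridError",
    "NoSteadyStateError",
]


class GridError(ValueError):
    """Raised when a trace is not on the uniform 1-minute grid."""


class NoSteadyStateError(ValueError):
    """Raised when a steady state does not exist (no cooling)."""


class Mode(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


# Quasi-linearity bound for the low-sensitivity placement: λ·30 min must stay
# well below 1 so a 30-minute bout cannot approach saturation.
_LOW_MODE_LAMBDA_MAX = 0.5 / 30.0
_HIGH_LOW_RATIO_MIN = 10.0


@dataclass(frozen=True)
class DeviceParams:
    """Physical parameters of one sensor placement.

    Parameters
    ----------
    mode
        Sensor placement, ``high`` or ``low`` sensitivity.
    gain_alpha
        Heating gain, °C per work-unit.
    cooling_lambda
        Newton cooling rate, 1/min.  High mode must cool at least 10× the
        low-mode default (so plateaus form within a bout); low mode must
        satisfy λ·30 < 0.5 (quasi-linear over 30 min).
    euler_step
        Integration substep in minutes, in (0, 1].
    noise_sd
        Default additive Gaussian sensor noise, °C.
    idle_cooling_lambda
        Cooling rate while the device is idle between sessions, 1/min.
        Idle cooling is ambient-convection driven and much faster than the
        in-exercise low-mode coupling constant.
    """

    mode: Mode = Mode.HIGH
    gain_alpha: float = 13.68
    cooling_lambda: float = 0.4
    euler_step: float = 0.1
    noise_sd: float = 0.1
    idle_cooling_lambda: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.gain_alpha <= 0:
            raise ValueError(f"gain_alpha must be > 0, got {self.gain_alpha}")
        if self.cooling_lambda < 0:
            raise ValueError(
                f"cooling_lambda must be >= 0, got {self.cooling_lambda}"
            )
        if not 0 < self.euler_step <= 1:
            raise ValueError(
                f"euler_step must be in (0, 1], got {self.euler_step}"
            )
        if self.mode is Mode.LOW and self.cooling_lambda >= _LOW_MODE_LAMBDA_MAX:
            raise ValueError(
                "low-sensitivity mode requires cooling_lambda*30 < 0.5 "
                f"(quasi-linear rise); got cooling_lambda={self.cooling_lambda}"
            )
        if (
            self.mode is Mode.HIGH
            and self.cooling_lambda
            < _HIGH_LOW_RATIO_MIN * LOW_SENSITIVITY_DEFAULTS["cooling_lambda"]
        ):
            raise ValueError(
                "high-sensitivity mode requires cooling_lambda >= "
                f"{_HIGH_LOW_RATIO_MIN}x the low-mode default"
            )

    def with_noise(self, noise_sd: float) -> "DeviceParams":
        return replace(self, noise_sd=noise_sd)


LOW_SENSITIVITY_DEFAULTS = {
    # Calibrated so a unit-power 30-minute bout accumulates exactly 8.1 degC:
    # alpha = 8.1 / ((1/lambda) * (1 - exp(-30*lambda)))
    "gain_alpha": 0.270810,
    "cooling_lambda": 0.0002,
    "noise_sd": 0.05,
}

HIGH_SENSITIVITY = DeviceParams(mode=Mode.HIGH)
LOW_SENSITIVITY = DeviceParams(mode=Mode.LOW, **LOW_SENSITIVITY_DEFAULTS)


def _check_minute_grid(times: np.ndarray, what: str) -> None:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise GridError(f"{what}: need a 1-D grid with >= 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise GridError(f"{what}: times must be strictly increasing")
    if not np.allclose(steps, 1.0, atol=1e-9):
        raise GridError(f"{what}: times must be on a uniform 1-minute grid")


@dataclass(frozen=True)
class SensorTrace:
    """Minute-sampled, baseline-zeroed Δt° series from one session."""

    times: np.ndarray
    delta_t: np.ndarray
    mode: Mode = Mode.HIGH

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        delta = np.asarray(self.delta_t, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "delta_t", delta)
        object.__setattr__(self, "mode", Mode(self.mode))
        _check_minute_grid(times, "SensorTrace")
        if delta.shape != times.shape:
            raise ValueError("times and delta_t must have the same shape")
        if not np.all(np.isfinite(delta)):
            raise ValueError("delta_t must be finite")
        if delta[0] > 0.5:
            raise ValueError(
                "trace is not baseline-zeroed (delta_t[0] "
                f"= {delta[0]:.2f} degC > 0.5)"
            )
        if np.any(delta < -0.5):
            raise ValueError("delta_t below -0.5 degC: not noise-compatible")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class PowerTrace:
    """Minute-sampled work-rate series (work-units per minute, >= 0)."""

    times: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "power", power)
        _check_minute_grid(times, "PowerTrace")
        if power.shape != times.shape:
            raise ValueError("times and power must have the same shape")
        if np.any(power < 0):
            raise ValueError("power must be >= 0 work-units/min")

    def __len__(self) -> int:
        return int(self.times.size)


def _integrate(
    power_minutes: np.ndarray, params: DeviceParams
) -> np.ndarray:
    """Integrate the heating ODE over a minute-gridded power series.

    Power is held piecewise-constant over each substep (zero-order hold of
    the minute samples), for which the exponential update

        Δ_{k+1} = Δ_k e^{-λh} + (α P_k / λ)(1 − e^{-λh})

    is exact; with λ=0 it degenerates to Δ_{k+1} = Δ_k + α P_k h.
    """
    h = params.euler_step
    lam = params.cooling_lambda
    alpha = params.gain_alpha
    n_min = power_minutes.size - 1
    sub = int(round(1.0 / h))
    # zero-order hold: substep i inside minute m uses P at the linear
    # interpolation of the minute samples (power varies within the minute)
    t_sub = np.arange(n_min * sub) * h
    p_sub = np.interp(t_sub, np.arange(n_min + 1, dtype=float), power_minutes)
    out = np.empty(n_min + 1)
    out[0] = 0.0
    delta = 0.0
    if lam > 0:
        decay = np.exp(-lam * h)
        gain = (1.0 - decay) / lam
        for k in range(n_min * sub):
            delta = delta * decay + alpha * p_sub[k] * gain
            if (k + 1) % sub == 0:
                out[(k + 1) // sub] = delta
    else:
        for k in range(n_min * sub):
            delta = delta + alpha * p_sub[k] * h
            if (k + 1) % sub == 0:
                out[(k + 1) // sub] = delta
    return out


def simulate_temperature(
    power: PowerTrace,
    params: DeviceParams,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> SensorTrace:
    """Forward-simulate the sensor's Δt° response to a work-rate trace.

    Parameters
    ----------
    power
        Work-rate trace on the uniform 1-minute grid.
    params
        Device calibration (mode, gain, cooling, integration step).
    noise_sd
        Additive Gaussian sensor noise in °C; ``None`` means noise-free.
        (``params.noise_sd`` is a convenience default for callers that want
        realistic noise; it is *not* applied implicitly.)
    rng
        Random generator for the noise; required when ``noise_sd`` > 0.
    """
    delta = _integrate(power.power, params)
    if noise_sd:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        noise = rng.normal(0.0, noise_sd, size=delta.size)
        noise[0] = 0.0  # traces are zeroed at session start by definition
        delta = np.clip(delta + noise, -0.49, None)
    return SensorTrace(times=power.times.copy(), delta_t=delta, mode=params.mode)


def steady_state_delta(power_level: float, params: DeviceParams) -> float:
    """Closed-form plateau Δ* = α·P/λ for a constant work rate."""
    if power_level < 0:
        raise ValueError("power_level must be >= 0")
    if params.cooling_lambda == 0:
        raise NoSteadyStateError(
            "cooling_lambda = 0: temperature grows without bound"
        )
    return params.gain_alpha * power_level / params.cooling_lambda


def estimate_power(
    trace: SensorTrace, params: DeviceParams, smooth_window: float = 3.0
) -> PowerTrace:
    """Invert the thermal model: recover the work-rate (LWO) signal.

    Rearranging the heating ODE, P̂(τ) = (dΔ/dτ + λ·Δ) / α.  The derivative
    is a centred moving-window least-squares slope of width ``smooth_window``
    minutes (a Savitzky–Golay degree-1 derivative filter), which suppresses
    the minute-level sensor noise.  Estimates are clipped at zero.
    """
    if len(trace) < 3:
        raise ValueError("estimate_power needs a trace of >= 3 samples")
    window = int(round(smooth_window))
    if window % 2 == 0:
        window += 1
    window = max(window, 3)
    if window > len(trace):
        raise ValueError(
            f"smooth_window ({window} samples) exceeds trace length "
            f"({len(trace)})"
        )
    slope = savgol_filter(
        trace.delta_t, window_length=window, polyorder=1, deriv=1, delta=1.0
    )
    power = (slope + params.cooling_lambda * trace.delta_t) / params.gain_alpha
    return PowerTrace(times=trace.times.copy(), power=np.clip(power, 0.0, None))
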
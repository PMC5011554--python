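"""Synthetic cohort and training-bout generator.

Emulates the study population: healthy adults performing moderate-intensity
continuous training (MICT) bouts on a resistance leg-training device while
device temperature (Δt°, the leg-work-output proxy) and heart rate are
recorded once per minute.  The generator plants known ground truth — work
rates, fatigue-onset times, a diurnal fatigability effect — so the analysis
layers (segmentation, dosimetry, fatigability) can be validated against it.

Model of a bout
---------------
* Heart-rate control (``hold_hr``): the participant holds a target HR; the
  recorded HR is the target plus minute-wise Gaussian jitter with SD 10 BPM
  (the band the study reports as "HR (SD 10) BPM").  The latent work rate
  starts at ``power_scale × intensity_map(target)`` and, once fatigue sets
  in, declines linearly at ``fatigue_decay_rate`` per minute; the combined
  fatigue/pacing loss is floored at ``fatigue_floor`` of the fresh rate.
* Power control (``hold_power``): the work rate is held constant; after
  fatigue onset the HR needed to sustain it drifts upward linearly toward
  HR_max (the study's variable-intensity bout).

Fatigue onset is linear in the heart-rate deficit below the vigorous
reference (130 BPM): onset = 7 min at HR 130 and 15 min at HR 120, i.e.
7 + 0.8·(130 − HR) minutes, giving 31 min at HR 100 — beyond a standard
30-minute MICT bout, which is therefore fatigue-free.

Evening sessions (at or after the 17:00 cutoff) model diurnal fatigability:
fatigue onset is divided by the participant's ``evening_factor`` and the
decay rate multiplied by it.

Between-bout variability mirrors the split-half time spreads the protocol is
designed to resolve: first-half (pre-fatigue) times vary by only a few
percent day to day, while post-fatigue times vary several-fold more.  Three
seeded jitters reproduce that structure: a day-effort multiplier on the work
rate (CV ``day_cv``), a slow within-bout pacing drift (slope SD
``pace_drift_sd`` per minute), and a per-bout lognormal multiplier on the
fatigue decay rate (CV ``decay_cv``).
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .device import (
    DeviceParams,
    Mode,
    PowerTrace,
    SensorTrace,
    simulate_temperature,
)

__all__ = [
    "Participant",
    "Regimen",
    "HRTrace",
    "TrainingBout",
    "SessionWindow",
    "ProgramSchedule",
    "ProgramResult",
    "intensity_map",
    "make_cohort",
    "simulate_bout",
    "simulate_program",
    "rpe_category",
    "fatigue_onset_minutes",
    "bout_seed",
    "EVENING_CUTOFF",
    "HOME_PARTICIPANT",
    "BoutTimeoutError",
]

EVENING_CUTOFF = dt.time(17, 0)

# HR targets anchored to relative work rates; reproduces the printed plateau
# ordering ~34 / ~51 / ~57 degC under the high-sensitivity calibration.
_INTENSITY_HR = np.array([100.0, 120.0, 130.0])
_INTENSITY_POWER = np.array([1.0, 1.5, 1.8])

_HR_REF = 130.0  # vigorous reference for the fatigue-onset law
_HOLD_POWER_ONSET_REF = 10.0  # min of moderate HR when holding unit work rate
_SAFETY_CAP_MIN = 120.0


class BoutTimeoutError(RuntimeError):
    """Dose not reached within the 120-minute safety cap."""


def intensity_map(hr_target: float) -> float:
    """Relative steady work rate a mean participant sustains at a target HR.

    Piecewise-linear through (100, 1.0), (120, 1.5), (130, 1.8) with edge
    slopes extended outside the anchors; clipped below at 0.2.
    """
    hr = float(hr_target)
    if hr <= _INTENSITY_HR[0]:
        p = 1.0 + (hr - 100.0) * (0.5 / 20.0)
    elif hr >= _INTENSITY_HR[-1]:
        p = 1.8 + (hr - 130.0) * (0.3 / 10.0)
    else:
        p = float(np.interp(hr, _INTENSITY_HR, _INTENSITY_POWER))
    return max(p, 0.2)


@dataclass(frozen=True)
class Participant:
    """One synthetic exerciser with planted fatigue characteristics."""

    id: str
    age: int = 45
    hr_rest: int = 65
    power_scale: float = 1.0
    fatigue_onset_ref: float = 7.0     # onset at the vigorous reference HR, min
    fatigue_slope: float = 0.8         # onset minutes gained per BPM below ref
    fatigue_decay_rate: float = 0.0217  # fraction of power lost per minute
    fatigue_floor: float = 0.45        # output never drops below this fraction
    evening_factor: float = 1.3        # >= 1; diurnal fatigability multiplier
    day_cv: float = 0.01               # day-to-day effort jitter (CV)
    pace_drift_sd: float = 0.0005      # SD of within-bout pacing drift, /min
    decay_cv: float = 0.03             # per-bout lognormal CV of the decay rate

    def __post_init__(self) -> None:
        if self.hr_rest >= self.hr_max:
            raise ValueError("hr_rest must be below hr_max")
        if self.power_scale <= 0:
            raise ValueError("power_scale must be > 0")
        if self.fatigue_onset_ref <= 0:
            raise ValueError("fatigue_onset_ref must be > 0")
        if self.evening_factor < 1:
            raise ValueError("evening_factor must be >= 1")

    @property
    def hr_max(self) -> int:
        """Age-predicted maximal heart rate, 220 − age."""
        return 220 - self.age


#: The strongly diurnal participant of the 8-week home program: trains at a
#: somewhat higher work rate (reaches the prescribed 10 degC dose in ~27 min
#: in the afternoon) and shows a pronounced evening fatigability effect.
HOME_PARTICIPANT = Participant(
    id="home", age=45, power_scale=1.3515, evening_factor=2.0
)


@dataclass(frozen=True)
class Regimen:
    """Prescription for one bout."""

    control: str = "hold_hr"           # hold_hr | hold_power
    target: float = 100.0              # BPM (hold_hr) or work-units/min
    duration: float = 30.0             # minutes (fixed_duration)
    stop_rule: str = "fixed_duration"  # fixed_duration | dose_reached
    dose_threshold: float | None = None  # degC, when stop_rule=dose_reached
    hr_sd: float = 10.0                # minute-wise HR control band

    def __post_init__(self) -> None:
        if self.control not in ("hold_hr", "hold_power"):
            raise ValueError(f"unknown control {self.control!r}")
        if self.stop_rule not in ("fixed_duration", "dose_reached"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.stop_rule == "dose_reached":
            if not self.dose_threshold or self.dose_threshold <= 0:
                raise ValueError("dose_reached requires dose_threshold > 0")
        elif self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class HRTrace:
    """Minute-sampled heart rate with %HR_max annotation."""

    times: np.ndarray
    bpm: np.ndarray
    hr_max: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        bpm = np.asarray(self.bpm, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "bpm", bpm)
        if bpm.shape != times.shape:
            raise ValueError("times and bpm must have the same shape")
        if np.any((bpm < 30) | (bpm > 230)):
            raise ValueError("bpm outside the physiologic range [30, 230]")

    @property
    def pct_hr_max(self) -> np.ndarray:
        return 100.0 * self.bpm / self.hr_max

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TrainingBout:
    """Paired sensor/HR recording of one session plus metadata.

    ``planted_onset`` is simulator ground truth (minutes; None when fatigue
    never set in during the exercise portion) used only for validation — the
    analysis modules never read it.
    """

    participant_id: str
    date: dt.date
    start_clock_time: dt.time
    sensor: SensorTrace
    hr: HRTrace | None
    exercise_end: float                      # minutes; recovery follows
    rpe_reported: int | None = None
    planted_onset: float | None = None
    planted_mechanism: str | None = None
    timed_out: bool = False

    def __post_init__(self) -> None:
        if self.hr is not None and len(self.sensor) != len(self.hr):
            raise ValueError("sensor and hr must cover the same interval")

    @property
    def is_evening(self) -> bool:
        return self.start_clock_time >= EVENING_CUTOFF


def rpe_category(score: float) -> str:
    """Band a Borg 6–20 rating: light (<12), moderate (12–14), strenuous (>14)."""
    if not 6 <= score <= 20:
        raise ValueError(f"Borg RPE must be in [6, 20], got {score}")
    if score < 12:
        return "light"
    if score <= 14:
        return "moderate"
    return "strenuous"


def fatigue_onset_minutes(
    p: Participant, hr_target: float, evening: bool = False
) -> float:
    """Planted fatigue-onset time for a target HR (minutes from bout start)."""
    onset = p.fatigue_onset_ref + p.fatigue_slope * (_HR_REF - hr_target)
    if evening:
        onset /= p.evening_factor
    return max(onset, 0.0)


def bout_seed(master_seed: int, participant_id: str, date: dt.date) -> int:
    """Stable per-bout seed from (participant, date) under one master seed."""
    key = f"{master_seed}|{participant_id}|{date.isoformat()}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def make_cohort(
    n: int,
    variability_cv: float = 0.17,
    seed: int | None = None,
    base: Participant | None = None,
) -> list[Participant]:
    """Draw a cohort with inter-individual work-rate variability.

    ``power_scale`` ~ Normal(1.0, variability_cv) truncated at 0.5 (redraw);
    all other fields are taken from ``base`` (config defaults).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    base = base or Participant(id="template")
    out: list[Participant] = []
    for i in range(n):
        scale = 1.0 if variability_cv == 0 else 0.0
        while scale <= 0.5:
            scale = rng.normal(1.0, variability_cv)
            if variability_cv == 0:
                scale = 1.0
        age = int(rng.integers(25, 53))  # study range 25-52 years
        out.append(replace(base, id=f"S{i + 1:02d}", age=age, power_scale=scale))
    return out


def _fatigued_power(
    p0: float, minutes: np.ndarray, onset: float, decay: float, floor: float
) -> np.ndarray:
    frac = np.where(
        minutes <= onset, 1.0, np.maximum(1.0 - decay * (minutes - onset), floor)
    )
    return p0 * frac


def _draw_rpe(rng: np.random.Generator, hr_target: float) -> int:
    # RPE bands reported in the study: moderate bouts 12-14, vigorous >14
    if hr_target >= 130:
        return int(rng.integers(15, 18))
    if hr_target >= 115:
        return int(rng.integers(13, 16))
    return int(rng.integers(12, 15))


def simulate_bout(
    p: Participant,
    r: Regimen,
    device: DeviceParams,
    clock_time: dt.time | str = dt.time(14, 0),
    date: dt.date = dt.date(2015, 3, 2),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    prior_exercise_min: float = 0.0,
    recovery_min: float = 0.0,
    hr_drift_rate: float = 1.5,
) -> TrainingBout:
    """Simulate one training session and its paired telemetry.

    ``prior_exercise_min`` models fatigue carried over from exercise just
    completed (the consecutive-dose experiment): fatigue onset is advanced by
    that many minutes.  ``noise_sd`` defaults to the device's calibration
    noise.  A ``dose_reached`` regimen ends one sample after Δt° first meets
    the threshold; if the threshold is unreachable within a 120-minute safety
    cap, the bout is returned flagged ``timed_out``.
    """
    if isinstance(clock_time, str):
        clock_time = dt.time.fromisoformat(clock_time)
    if rng is None:
        rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = device.noise_sd
    evening = clock_time >= EVENING_CUTOFF

    day_effort = 0.0
    while day_effort <= 0.5:
        day_effort = 1.0 if p.day_cv == 0 else rng.normal(1.0, p.day_cv)
    pace_slope = rng.normal(0.0, p.pace_drift_sd) if p.pace_drift_sd else 0.0
    if p.decay_cv:
        sigma = np.sqrt(np.log1p(p.decay_cv**2))
        decay_jitter = rng.lognormal(-(sigma**2) / 2.0, sigma)
    else:
        decay_jitter = 1.0
    decay = (
        p.fatigue_decay_rate
        * decay_jitter
        * (p.evening_factor if evening else 1.0)
    )

    if r.stop_rule == "fixed_duration":
        horizon = r.duration
    else:
        horizon = _SAFETY_CAP_MIN
    n_min = int(np.ceil(horizon))
    minutes = np.arange(n_min + 1, dtype=float)

    if r.control == "hold_hr":
        onset = fatigue_onset_minutes(p, r.target, evening)
        onset = max(onset - prior_exercise_min, 0.0)
        p0 = p.power_scale * day_effort * intensity_map(r.target)
        frac = _fatigued_power(1.0, minutes, onset, decay, 0.0)
        frac = frac * (1.0 + pace_slope * minutes)
        # the floor caps the *combined* loss: output never drops below the
        # floor fraction of the fresh work rate
        power = p0 * np.clip(frac, p.fatigue_floor, None)
        bpm = r.target + rng.normal(0.0, r.hr_sd, size=minutes.size)
        mechanism = "lwo_decline_steady_hr"
    else:  # hold_power
        p0 = p.power_scale * day_effort * r.target
        power = np.full(minutes.size, p0)
        # start HR consistent with the held work rate for a mean participant
        hr0 = float(
            np.interp(
                r.target, _INTENSITY_POWER, _INTENSITY_HR,
                left=100.0 - (1.0 - r.target) * 40.0, right=130.0,
            )
        )
        # holding the work rate constant denies the natural post-fatigue
        # decline, so intensity must rise much sooner than under HR control:
        # anchored to the variable-intensity bout, where HR stayed moderate
        # for only ~10 minutes at the unit work rate
        onset = _HOLD_POWER_ONSET_REF / max(r.target, 0.2)
        if evening:
            onset /= p.evening_factor
        onset = max(onset - prior_exercise_min, 0.0)
        drift = np.maximum(minutes - onset, 0.0) * hr_drift_rate
        bpm = np.minimum(hr0 + drift, p.hr_max) + rng.normal(
            0.0, r.hr_sd, size=minutes.size
        )
        mechanism = "hr_rise_steady_lwo"

    sensor = simulate_temperature(
        PowerTrace(times=minutes, power=power), device, noise_sd=noise_sd,
        rng=rng,
    )

    timed_out = False
    if r.stop_rule == "dose_reached":
        crossed = np.nonzero(sensor.delta_t >= r.dose_threshold)[0]
        if crossed.size == 0:
            timed_out = True
            end_idx = n_min
        else:
            end_idx = min(int(crossed[0]) + 1, n_min)
        minutes = minutes[: end_idx + 1]
        sensor = SensorTrace(
            times=minutes, delta_t=sensor.delta_t[: end_idx + 1],
            mode=sensor.mode,
        )
        bpm = bpm[: end_idx + 1]
        power = power[: end_idx + 1]

    exercise_end = float(minutes[-1])
    if recovery_min > 0 and r.stop_rule == "fixed_duration":
        extra = int(np.ceil(recovery_min))
        all_minutes = np.arange(minutes.size + extra, dtype=float)
        power_full = np.concatenate([power, np.zeros(extra)])
        sensor = simulate_temperature(
            PowerTrace(times=all_minutes, power=power_full), device,
            noise_sd=noise_sd, rng=rng,
        )
        # HR relaxes exponentially toward rest after cessation
        rec_t = np.arange(1, extra + 1, dtype=float)
        hr_end = bpm[-1]
        rec = p.hr_rest + (hr_end - p.hr_rest) * np.exp(-0.25 * rec_t)
        bpm = np.concatenate([bpm, rec + rng.normal(0, 3.0, size=extra)])
        minutes = all_minutes

    bpm = np.clip(np.round(bpm), 30, 230)
    planted = onset if onset < exercise_end else None
    return TrainingBout(
        participant_id=p.id,
        date=date,
        start_clock_time=clock_time,
        sensor=sensor,
        hr=HRTrace(times=minutes, bpm=bpm, hr_max=p.hr_max),
        exercise_end=exercise_end,
        rpe_reported=_draw_rpe(rng, r.target if r.control == "hold_hr" else 100),
        planted_onset=planted,
        planted_mechanism=mechanism if planted is not None else None,
        timed_out=timed_out,
    )


@dataclass(frozen=True)
class SessionWindow:
    """Clock-time window in which a session may start on matching weekdays."""

    weekdays: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)  # Monday=0
    tod: str = "afternoon"               # afternoon | evening
    start: dt.time = dt.time(13, 0)
    end: dt.time = dt.time(16, 30)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tod not in ("afternoon", "evening"):
            raise ValueError(f"unknown time-of-day tag {self.tod!r}")


AFTERNOON_WINDOW = SessionWindow()
EVENING_WINDOW = SessionWindow(
    tod="evening", start=dt.time(18, 0), end=dt.time(21, 30)
)


@dataclass(frozen=True)
class ProgramSchedule:
    """Multi-week home-training schedule."""

    weeks: int = 1
    session_windows: tuple[SessionWindow, ...] = (
        replace(AFTERNOON_WINDOW, weight=0.7),
        replace(EVENING_WINDOW, weight=0.3),
    )
    adherence_prob: float = 0.6
    seed: int = 0
    start_date: dt.date = dt.date(2015, 3, 2)
    n_days: int | None = None            # overrides weeks*7 when set
    skip_days: frozenset[int] = field(default_factory=frozenset)
    # 1-based day numbers; when non-empty, adherence draws are skipped and
    # every other day is trained (the deterministic printed-schedule case)

    def __post_init__(self) -> None:
        if not 0 <= self.adherence_prob <= 1:
            raise ValueError("adherence_prob must be in [0, 1]")
        if self.weeks < 1 and self.n_days is None:
            raise ValueError("schedule must cover at least one week or set n_days")

    @property
    def total_days(self) -> int:
        return self.n_days if self.n_days is not None else self.weeks * 7


@dataclass(frozen=True)
class ProgramResult:
    """Bouts of a home program plus the continuous multi-day device trace."""

    bouts: list[TrainingBout]
    trace_minutes: np.ndarray    # minutes from program start (day 1, 00:00)
    trace_delta_t: np.ndarray    # continuous degC trace incl. idle cooling
    trained_days: list[dt.date]
    skipped_days: list[dt.date]


def _draw_clock(rng: np.random.Generator, w: SessionWindow) -> dt.time:
    lo = w.start.hour * 60 + w.start.minute
    hi = w.end.hour * 60 + w.end.minute
    m = int(rng.integers(lo, hi + 1))
    return dt.time(m // 60, m % 60)


def simulate_program(
    p: Participant,
    sched: ProgramSchedule,
    r: Regimen,
    device: DeviceParams,
) -> ProgramResult:
    """Simulate a multi-day home program and the continuous device recording.

    One bout is simulated per trained day at a clock time drawn from that
    day's window; the continuous trace concatenates the per-session
    (baseline-zeroed) recordings with exponential idle cooling in between.
    Fully deterministic under ``sched.seed``: per-bout randomness derives
    from a stable hash of (participant, date).
    """
    if not sched.session_windows:
        raise ValueError("schedule has no session windows")
    day_rng = np.random.default_rng(sched.seed)

    n_days = sched.total_days
    grid = np.arange(n_days * 1440 + 1, dtype=float)
    cont = np.zeros(grid.size)
    baseline = 0.0
    cursor = 0  # index into grid up to which cont is filled
    lam_idle = device.idle_cooling_lambda

    bouts: list[TrainingBout] = []
    trained: list[dt.date] = []
    skipped: list[dt.date] = []

    for day in range(1, n_days + 1):
        date = sched.start_date + dt.timedelta(days=day - 1)
        windows = [w for w in sched.session_windows if date.weekday() in w.weekdays]
        if sched.skip_days:
            train_today = day not in sched.skip_days and bool(windows)
        else:
            train_today = bool(windows) and (
                day_rng.random() < sched.adherence_prob
            )
        if not train_today:
            skipped.append(date)
            continue
        weights = np.array([w.weight for w in windows])
        w = windows[day_rng.choice(len(windows), p=weights / weights.sum())]
        clock = _draw_clock(day_rng, w)
        brng = np.random.default_rng(bout_seed(sched.seed, p.id, date))
        bout = simulate_bout(
            p, r, device, clock_time=clock, date=date, rng=brng
        )
        bouts.append(bout)
        trained.append(date)

        start_min = (day - 1) * 1440 + clock.hour * 60 + clock.minute
        # idle cooling from the previous cursor to this session's start
        idle_t = grid[cursor : start_min + 1] - grid[cursor]
        cont[cursor : start_min + 1] = baseline * np.exp(-lam_idle * idle_t)
        pre = cont[start_min]
        n = len(bout.sensor)
        cont[start_min : start_min + n] = pre + bout.sensor.delta_t
        cursor = start_min + n - 1
        baseline = cont[cursor]

    idle_t = grid[cursor:] - grid[cursor]
    cont[cursor:] = baseline * np.exp(-lam_idle * idle_t)
    return ProgramResult(
        bouts=bouts,
        trace_minutes=grid,
        trace_delta_t=cont,
        trained_days=trained,
        skipped_days=skipped,
    )
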
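"""Personalized exercise-dose calibration and dose-taking tracking.

In low-sensitivity mode Δt° rises quasi-linearly over a 30-minute bout, so
the value reached integrates the work done.  The *personalized dose* of
daily moderate-intensity continuous training (MICT) is defined as the Δt°
a participant reaches in a 30-minute fatigue-free moderate bout; on later
days, reaching that threshold counts as "taking" the dose and fires a
notification (modelled here as a logged event with a timestamp, never an
actual email).  Because the low-mode trace is near-linear, shorter or longer
fatigue-free bouts map onto dose fractions proportional to duration
(15/30/60 min ↔ 0.5/1.0/2.0 doses).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .cohort import TrainingBout
from .device import Mode, SensorTrace
from .segmentation import FatigueAssessment

__all__ = [
    "DosePrescription",
    "DoseEvent",
    "CalibrationRefusedError",
    "BaselineError",
    "calibrate_dose",
    "track_dose",
    "dose_fraction",
    "split_sessions",
]


class CalibrationRefusedError(ValueError):
    """The calibration bout does not meet the fatigue-free dosing rule."""


class BaselineError(ValueError):
    """The trace was not zeroed at session start."""


@dataclass(frozen=True)
class DosePrescription:
    """A participant's personalized daily MICT dose threshold."""

    participant_id: str
    threshold_c: float
    calibrated_from: str = ""
    calibrated_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.threshold_c <= 0:
            raise ValueError("threshold_c must be > 0")

    def display_threshold(self, whole_degrees: bool = False) -> float:
        """Threshold for display; optionally rounded to whole °C as in the
        10 °C home-program prescription."""
        return round(self.threshold_c) if whole_degrees else self.threshold_c


@dataclass(frozen=True)
class DoseEvent:
    """One dose-taking attempt: half/full threshold-crossing times."""

    participant_id: str
    date: dt.date
    start_clock_time: dt.time
    threshold_c: float
    t_half: float | None   # minutes to threshold/2 (interpolated, 0.1 min)
    t_full: float | None   # minutes to threshold
    notified_at: dt.time | None
    completed: bool

    def __post_init__(self) -> None:
        if self.completed:
            if not (self.t_half and self.t_full and 0 < self.t_half < self.t_full):
                raise ValueError(
                    "completed event requires 0 < t_half < t_full"
                )
            if self.notified_at is None:
                raise ValueError("completed event must carry a notification")


def calibrate_dose(
    bout: TrainingBout, assessment: FatigueAssessment
) -> DosePrescription:
    """Derive a personalized dose from a 30-minute fatigue-free MICT bout.

    The prescription threshold is the Δt° at minute 30 of the bout, rounded
    to 0.1 °C.  Calibration is refused if the bout was not fatigue-free, ran
    shorter than 30 minutes, or was not recorded in low-sensitivity mode —
    dosing is only meaningful on the quasi-linear signal of a bout the
    participant completed at steady output.
    """
    if not assessment.fatigue_free:
        raise CalibrationRefusedError(
            "calibration requires a fatigue-free bout (mechanism="
            f"{assessment.mechanism}, onset={assessment.onset_minute})"
        )
    if bout.exercise_end < 30:
        raise CalibrationRefusedError(
            f"calibration bout must cover >= 30 min, got {bout.exercise_end}"
        )
    if bout.sensor.mode is not Mode.LOW:
        raise CalibrationRefusedError(
            "calibration requires a low-sensitivity recording"
        )
    at30 = float(np.interp(30.0, bout.sensor.times, bout.sensor.delta_t))
    threshold = round(at30, 1)
    if threshold <= 0:
        raise CalibrationRefusedError(
            f"no measurable work output in the calibration bout ({at30:.2f} degC)"
        )
    return DosePrescription(
        participant_id=bout.participant_id,
        threshold_c=threshold,
        calibrated_from=f"{bout.participant_id}@{bout.date.isoformat()}",
        calibrated_date=bout.date,
    )


def _crossing_time(times: np.ndarray, delta: np.ndarray, level: float) -> float | None:
    """First time Δt° reaches ``level``, linearly interpolated, 0.1-min grid."""
    above = np.nonzero(delta >= level)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return 0.0
    t0, t1 = times[i - 1], times[i]
    d0, d1 = delta[i - 1], delta[i]
    t = t0 + (level - d0) / (d1 - d0) * (t1 - t0)
    return round(float(t), 1)


def track_dose(
    trace: SensorTrace,
    rx: DosePrescription,
    start_clock_time: dt.time | str,
    date: dt.date = dt.date(2015, 3, 2),
) -> DoseEvent:
    """Track one session against a prescription and log the notification.

    ``t_half``/``t_full`` are the first (linearly interpolated) minutes at
    which Δt° reaches half and the full threshold; the single notification is
    stamped ``start + t_full``.  An event whose threshold is never reached is
    returned with ``completed=False``.  Re-running on the same trace yields an
    identical event (notifications are debounced by construction: one crossing
    time exists per trace).
    """
    if isinstance(start_clock_time, str):
        start_clock_time = dt.time.fromisoformat(start_clock_time)
    if trace.delta_t[0] > 0.5:
        raise BaselineError(
            f"trace starts at {trace.delta_t[0]:.2f} degC; sessions must be "
            "baseline-zeroed"
        )
    t_half = _crossing_time(trace.times, trace.delta_t, rx.threshold_c / 2.0)
    t_full = _crossing_time(trace.times, trace.delta_t, rx.threshold_c)
    completed = t_full is not None
    notified_at = None
    if completed:
        anchor = dt.datetime.combine(date, start_clock_time)
        notified_at = (anchor + dt.timedelta(minutes=t_full)).time()
    return DoseEvent(
        participant_id=rx.participant_id,
        date=date,
        start_clock_time=start_clock_time,
        threshold_c=rx.threshold_c,
        t_half=t_half,
        t_full=t_full if completed else None,
        notified_at=notified_at,
        completed=completed,
    )


def dose_fraction(
    bout_duration: float, rx_reference_duration: float = 30.0
) -> float:
    """Dose fraction of a fatigue-free constant-LWO bout vs the 30-min reference.

    Valid under the low-mode quasi-linearity assumption (Δt° ∝ duration at
    constant work rate), under which 15/30/60-minute bouts correspond to
    0.5/1.0/2.0 daily doses.
    """
    if bout_duration <= 0 or rx_reference_duration <= 0:
        raise ValueError("durations must be > 0")
    return bout_duration / rx_reference_duration


def split_sessions(
    minutes: np.ndarray,
    delta_t: np.ndarray,
    cool_threshold_c: float = 0.5,
    min_gap_min: float = 60.0,
    mode: Mode = Mode.LOW,
) -> list[tuple[float, SensorTrace]]:
    """Split a continuous multi-day trace into per-session zeroed traces.

    A session boundary is any gap during which the device cooled below
    ``cool_threshold_c`` for at least ``min_gap_min`` minutes; each session
    trace is re-zeroed to its own start (the study's per-session convention)
    and returned with its start offset in minutes from the recording start.
    """
    minutes = np.asarray(minutes, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    cold = delta_t < cool_threshold_c
    sessions: list[tuple[float, SensorTrace]] = []
    i, n = 0, minutes.size
    while i < n:
        if cold[i]:
            i += 1
            continue
        # session start: last cold sample before activity
        start = max(i - 1, 0)
        j = i
        run_cold = 0
        while j < n:
            run_cold = run_cold + 1 if cold[j] else 0
            if run_cold >= min_gap_min:
                break
            j += 1
        end = j - run_cold + 1 if run_cold else n
        seg_t = minutes[start:end] - minutes[start]
        seg_d = delta_t[start:end] - delta_t[start]
        if seg_t.size >= 2 and seg_d.max() > cool_threshold_c:
            sessions.append(
                (float(minutes[start]), SensorTrace(seg_t, seg_d, mode=mode))
            )
        i = end
    return sessions
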
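"""Readers and writers for trace, event, and metadata formats.

All telemetry is exchanged as plain CSV on the session-relative 1-minute
grid: sensor files with header ``minute,delta_t_c`` and heart-rate files with
``minute,bpm``.  Absolute timestamps (ISO-8601 date, HH:MM clock time) live
only in the session-metadata JSON-lines records, matching the device's
per-session zeroing convention.  Readers validate and gently repair real-world
artifacts: a constant positive baseline offset up to 0.5 °C is re-zeroed with
a logged warning, and single-minute gaps are linearly interpolated; larger
gaps are parse errors naming the offending row.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import HRTrace, TrainingBout
from .device import Mode, SensorTrace
from .dosimetry import DoseEvent

__all__ = [
    "ParseError",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_hr_csv",
    "write_hr_csv",
    "write_dose_events_csv",
    "read_dose_events_csv",
    "write_session_metadata",
    "read_session_metadata",
    "write_segmentation_report",
]

log = logging.getLogger("legwork")

SENSOR_COLUMNS = ["minute", "delta_t_c"]
HR_COLUMNS = ["minute", "bpm"]
EVENT_COLUMNS = [
    "participant_id", "date", "start_time", "threshold_c",
    "t_half_min", "t_full_min", "notified_at", "completed",
]
MAX_GAP_MIN = 2


class ParseError(ValueError):
    pass


def _read_minute_frame(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    minutes = df["minute"].to_numpy()
    diffs = np.diff(minutes)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise ParseError(
            f"{path}: non-monotone minutes at row {int(bad[0]) + 2} "
            f"(minute {minutes[bad[0] + 1]})"
        )
    gaps = np.nonzero(diffs > MAX_GAP_MIN)[0]
    if gaps.size:
        raise ParseError(
            f"{path}: gap of {int(diffs[gaps[0]])} min after row "
            f"{int(gaps[0]) + 2} exceeds the {MAX_GAP_MIN}-min limit"
        )
    return df


def _regrid(minutes: np.ndarray, values: np.ndarray, path: Path) -> tuple[np.ndarray, np.ndarray]:
    full = np.arange(minutes[0], minutes[-1] + 1, dtype=float)
    if full.size != minutes.size:
        log.warning(
            "%s: %d missing minute(s) linearly interpolated",
            path, full.size - minutes.size,
        )
        values = np.interp(full, minutes.astype(float), values)
    return full, np.asarray(values, dtype=float)


def read_sensor_csv(path: str | Path, mode: Mode | str = Mode.LOW) -> SensorTrace:
    """Read one session's Δt° trace, re-zeroing a small baseline offset."""
    path = Path(path)
    df = _read_minute_frame(path, SENSOR_COLUMNS)
    minutes, delta = _regrid(
        df["minute"].to_numpy(), df["delta_t_c"].to_numpy(float), path
    )
    if 0 < delta[0] <= 0.5:
        log.warning(
            "%s: baseline offset of %.2f degC removed (sessions are zeroed)",
            path, delta[0],
        )
        delta = delta - delta[0]
    elif delta[0] > 0.5:
        raise ParseError(
            f"{path}: starting offset {delta[0]:.2f} degC exceeds the 0.5 degC "
            "baseline-correction limit; trace is not session-zeroed"
        )
    minutes = minutes - minutes[0]
    return SensorTrace(times=minutes, delta_t=delta, mode=Mode(mode))


def write_sensor_csv(trace: SensorTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "minute": trace.times.astype(int),
            "delta_t_c": np.round(trace.delta_t, 3),
        }
    ).to_csv(path, index=False)


def read_hr_csv(path: str | Path, participant_age: int) -> HRTrace:
    """Read a minute-averaged heart-rate export; %HR_max uses 220 − age."""
    path = Path(path)
    df = _read_minute_frame(path, HR_COLUMNS)
    bpm = df["bpm"].to_numpy(float)
    bad = np.nonzero((bpm < 30) | (bpm > 230))[0]
    if bad.size:
        raise ParseError(
            f"{path}: bpm {bpm[bad[0]]:g} at row {int(bad[0]) + 2} outside "
            "the physiologic range [30, 230]"
        )
    minutes, bpm = _regrid(df["minute"].to_numpy(), bpm, path)
    return HRTrace(
        times=minutes - minutes[0], bpm=bpm, hr_max=220 - int(participant_age)
    )


def write_hr_csv(hr: HRTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"minute": hr.times.astype(int), "bpm": hr.bpm.astype(int)}
    ).to_csv(path, index=False)


def write_dose_events_csv(events: list[DoseEvent], path: str | Path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "date": e.date.isoformat(),
            "start_time": e.start_clock_time.isoformat(timespec="minutes"),
            "threshold_c": e.threshold_c,
            "t_half_min": e.t_half,
            "t_full_min": e.t_full,
            "notified_at": (
                e.notified_at.isoformat(timespec="minutes")
                if e.notified_at else ""
            ),
            "completed": e.completed,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_dose_events_csv(path: str | Path) -> list[DoseEvent]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    events = []
    for _, row in df.iterrows():
        completed = bool(row["completed"])
        events.append(
            DoseEvent(
                participant_id=str(row["participant_id"]),
                date=dt.date.fromisoformat(row["date"]),
                start_clock_time=dt.time.fromisoformat(row["start_time"]),
                threshold_c=float(row["threshold_c"]),
                t_half=float(row["t_half_min"])
                if pd.notna(row["t_half_min"]) else None,
                t_full=float(row["t_full_min"])
                if completed and pd.notna(row["t_full_min"]) else None,
                notified_at=(
                    dt.time.fromisoformat(str(row["notified_at"]))
                    if completed and pd.notna(row["notified_at"])
                    and str(row["notified_at"]) else None
                ),
                completed=completed,
            )
        )
    return events


def write_session_metadata(bouts: list[TrainingBout], path: str | Path) -> None:
    """One JSON-lines record per bout (absolute timestamps live here)."""
    with open(path, "w") as fh:
        for b in bouts:
            fh.write(
                json.dumps(
                    {
                        "participant_id": b.participant_id,
                        "date": b.date.isoformat(),
                        "start_time": b.start_clock_time.isoformat(
                            timespec="minutes"
                        ),
                        "mode": b.sensor.mode.value,
                        "exercise_end_min": b.exercise_end,
                        "rpe": b.rpe_reported,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_session_metadata(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_segmentation_report(rows: list[dict], path: str | Path) -> None:
    """Segmentation report: one row per bout with boundaries and assessment."""
    cols = [
        "bout_id", "t1", "t2", "t3", "t4",
        "fatigue_free", "onset_minute", "mechanism",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
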
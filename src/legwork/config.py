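"""Study configuration: defaults, YAML loading, and object builders.

The configuration mirrors the study conditions: device calibrations for both
sensor placements, the cohort spread, the planted fatigue law, the home
schedule, and the analysis tolerances.  Unknown keys are rejected with a
warning listing them, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import copy
import datetime as dt
import warnings
from pathlib import Path
from typing import Any

import yaml

from .cohort import Participant
from .device import (
    DeviceParams,
    HIGH_SENSITIVITY,
    LOW_SENSITIVITY,
    Mode,
)
from .segmentation import FatigueCriteria

__all__ = ["DEFAULT_CONFIG", "load_config", "StudyConfig"]

DEFAULT_CONFIG: dict[str, Any] = {
    "device": {
        "mode": "low",
        "gain_alpha": None,        # None -> mode default
        "cooling_lambda": None,
        "noise_sd": None,
        "euler_step": 0.1,
    },
    "cohort": {
        "n": 7,
        "variability_cv": 0.17,
    },
    "fatigue": {
        "onset_ref": 7.0,
        "slope": 0.8,
        "decay_rate": 0.0217,
        "evening_factor": 1.3,
        "day_cv": 0.01,
        "pace_drift_sd": 0.0005,
        "decay_cv": 0.03,
    },
    "schedule": {
        "adherence_prob": 0.6,
        "weeks": 1,
    },
    "analysis": {
        "smooth_window": None,   # None -> mode default (3 high / 7 low)
        "hr_drift_tol": 15.0,
        "lwo_drop_tol": 0.10,
        "persistence": 3,
        "cutoff": "17:00",
        "test": "welch",
    },
    "seeds": {
        "master": 17,
    },
    "output_dir": "results",
}


def _merge(defaults: dict, user: dict, prefix: str = "") -> tuple[dict, list[str]]:
    out = copy.deepcopy(defaults)
    unknown: list[str] = []
    for key, val in (user or {}).items():
        where = f"{prefix}{key}"
        if key not in defaults:
            unknown.append(where)
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key], sub = _merge(defaults[key], val, prefix=f"{where}.")
            unknown.extend(sub)
        else:
            out[key] = val
    return out, unknown


class StudyConfig:
    """Validated study configuration with typed object builders."""

    def __init__(self, data: dict[str, Any] | None = None):
        merged, unknown = _merge(DEFAULT_CONFIG, data or {})
        if unknown:
            warnings.warn(
                f"ignoring unknown config key(s): {', '.join(sorted(unknown))}",
                stacklevel=2,
            )
        self.data = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def master_seed(self) -> int:
        return int(self.data["seeds"]["master"])

    def device_params(self, mode: Mode | str | None = None) -> DeviceParams:
        dev = self.data["device"]
        mode = Mode(mode or dev["mode"])
        base = HIGH_SENSITIVITY if mode is Mode.HIGH else LOW_SENSITIVITY
        kwargs = {}
        for key in ("gain_alpha", "cooling_lambda", "noise_sd", "euler_step"):
            if dev.get(key) is not None:
                kwargs[key] = dev[key]
        if not kwargs:
            return base
        from dataclasses import replace

        return replace(base, **kwargs)

    def base_participant(self, pid: str = "template") -> Participant:
        f = self.data["fatigue"]
        return Participant(
            id=pid,
            fatigue_onset_ref=f["onset_ref"],
            fatigue_slope=f["slope"],
            fatigue_decay_rate=f["decay_rate"],
            evening_factor=f["evening_factor"],
            day_cv=f["day_cv"],
            pace_drift_sd=f["pace_drift_sd"],
            decay_cv=f["decay_cv"],
        )

    def fatigue_criteria(self) -> FatigueCriteria:
        a = self.data["analysis"]
        return FatigueCriteria(
            hr_drift_tol=a["hr_drift_tol"],
            lwo_drop_tol=a["lwo_drop_tol"],
            persistence=int(a["persistence"]),
            smooth_window=a["smooth_window"],
        )

    @property
    def cutoff(self) -> dt.time:
        return dt.time.fromisoformat(self.data["analysis"]["cutoff"])


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML config over the defaults (``None`` → pure defaults)."""
    if path is None:
        return StudyConfig()
    return StudyConfig.from_yaml(path)
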
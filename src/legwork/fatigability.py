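"""Retrospective fatigability statistics over dose events.

Fatigability — susceptibility to fatigue — is quantified retrospectively by
how much longer the *second* half of a dose takes than the first.  A dose
event's split-half times are t_first = time to reach half the threshold and
t_second = time from half to full threshold; their sum is the total bout
duration (an exact identity).  Because the first half of a bout is performed
fresh, t_first is stable day to day, and any lengthening of the total is
carried by t_second — the fatigue signature.  Grouping events by start time
relative to a 17:00 cutoff ("afternoon" vs "evening") exposes the diurnal
pattern: similar first halves in both groups, but longer second halves and
totals in the evening.

Comparisons are Welch (unequal-variance) two-sample t tests by default, with
a label-permutation alternative; significance is reported at 0.05 with no
multiple-comparison correction (the number of tests is footnoted in the
report).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dosimetry import DoseEvent

__all__ = [
    "GroupStats",
    "Comparison",
    "FatigabilityReport",
    "split_half_times",
    "percent_longer",
    "diurnal_compare",
    "compliance_summary",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = dt.time(17, 0)
ALPHA = 0.05


class IncompleteEventError(ValueError):
    """Split-half times are undefined for an incomplete dose event."""


def split_half_times(event: DoseEvent) -> tuple[float, float]:
    """(t_first, t_second) = (t_half, t_full − t_half) of a completed event."""
    if not event.completed:
        raise IncompleteEventError(
            f"event {event.participant_id}@{event.date} did not reach its "
            "threshold; excluded from split-half statistics"
        )
    return float(event.t_half), float(event.t_full - event.t_half)


def percent_longer(mean_first: float, mean_second: float) -> float:
    """Percent by which the mean second half-dose time exceeds the first."""
    if mean_first <= 0:
        raise ValueError("mean_first must be > 0")
    return 100.0 * (mean_second - mean_first) / mean_first


@dataclass(frozen=True)
class GroupStats:
    """Split-half summaries of one diurnal group."""

    name: str
    n: int
    mean_first: float
    sd_first: float
    mean_second: float
    sd_second: float
    mean_total: float
    sd_total: float
    percent_longer: float
    sufficient: bool = True


@dataclass(frozen=True)
class Comparison:
    """One two-sample comparison with its p-value."""

    label: str
    statistic: float
    p_value: float
    significant: bool
    skipped: bool = False
    note: str = ""


@dataclass(frozen=True)
class FatigabilityReport:
    """Grouped split-half statistics and between/within-group comparisons."""

    afternoon: GroupStats
    evening: GroupStats
    comparisons: tuple[Comparison, ...]
    cutoff: dt.time
    test: str
    n_events_total: int
    n_excluded_incomplete: int
    compliance_days_per_week: tuple[float, float] | None = None  # mean, SD
    n_tests_footnote: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_tests_footnote",
            sum(1 for c in self.comparisons if not c.skipped),
        )

    def to_dict(self) -> dict:
        def g(s: GroupStats) -> dict:
            return {
                "n": s.n,
                "t_first_mean": round(s.mean_first, 2),
                "t_first_sd": round(s.sd_first, 2),
                "t_second_mean": round(s.mean_second, 2),
                "t_second_sd": round(s.sd_second, 2),
                "t_total_mean": round(s.mean_total, 2),
                "t_total_sd": round(s.sd_total, 2),
                "percent_longer": round(s.percent_longer, 1),
                "sufficient": s.sufficient,
            }

        return {
            "cutoff": self.cutoff.isoformat(timespec="minutes"),
            "test": self.test,
            "afternoon": g(self.afternoon),
            "evening": g(self.evening),
            "comparisons": [
                {
                    "label": c.label,
                    "statistic": None if c.skipped else round(c.statistic, 3),
                    "p_value": None if c.skipped else round(c.p_value, 4),
                    "significant": c.significant,
                    "skipped": c.skipped,
                    "note": c.note,
                }
                for c in self.comparisons
            ],
            "n_events_total": self.n_events_total,
            "n_excluded_incomplete": self.n_excluded_incomplete,
            "n_tests_uncorrected": self.n_tests_footnote,
            "compliance_days_per_week": (
                None
                if self.compliance_days_per_week is None
                else [round(v, 2) for v in self.compliance_days_per_week]
            ),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"Fatigability report (cutoff {d['cutoff']}, {d['test']} test)",
            f"{'group':<10}{'n':>4}{'first':>14}{'second':>14}{'total':>14}"
            f"{'%longer':>9}",
        ]
        for name in ("afternoon", "evening"):
            s = d[name]
            lines.append(
                f"{name:<10}{s['n']:>4}"
                f"{s['t_first_mean']:>8.1f} ({s['t_first_sd']:.1f})"
                f"{s['t_second_mean']:>8.1f} ({s['t_second_sd']:.1f})"
                f"{s['t_total_mean']:>8.1f} ({s['t_total_sd']:.1f})"
                f"{s['percent_longer']:>8.1f}%"
            )
        for c in d["comparisons"]:
            if c["skipped"]:
                lines.append(f"  {c['label']}: skipped ({c['note']})")
            else:
                star = " *" if c["significant"] else ""
                lines.append(
                    f"  {c['label']}: p = {c['p_value']:.4f}{star}"
                )
        lines.append(
            f"  ({d['n_tests_uncorrected']} uncorrected tests; "
            f"{d['n_excluded_incomplete']} incomplete events excluded)"
        )
        if d["compliance_days_per_week"]:
            m, s = d["compliance_days_per_week"]
            lines.append(f"  compliance: {m:.1f} (SD {s:.1f}) days/week")
        return "\n".join(lines)


def _two_sample(
    a: np.ndarray, b: np.ndarray, label: str, test: str,
    rng: np.random.Generator | None,
) -> Comparison:
    if a.size < 2 or b.size < 2:
        return Comparison(label, np.nan, np.nan, False, skipped=True,
                          note="insufficient events")
    if np.var(a) == 0 and np.var(b) == 0:
        return Comparison(label, np.nan, np.nan, False, skipped=True,
                          note="zero variance in both samples")
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return Comparison(label, float(res.statistic), float(res.pvalue),
                          bool(res.pvalue < ALPHA))
    # permutation test on the difference of means
    res = stats.permutation_test(
        (a, b),
        lambda x, y: np.mean(x) - np.mean(y),
        permutation_type="independent",
        n_resamples=2000,
        rng=rng,
    )
    return Comparison(label, float(res.statistic), float(res.pvalue),
                      bool(res.pvalue < ALPHA))


def _group_stats(name: str, first: np.ndarray, second: np.ndarray) -> GroupStats:
    n = first.size
    if n == 0:
        return GroupStats(name, 0, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, np.nan, sufficient=False)
    total = first + second
    return GroupStats(
        name=name,
        n=n,
        mean_first=float(first.mean()),
        sd_first=float(first.std(ddof=1)) if n > 1 else 0.0,
        mean_second=float(second.mean()),
        sd_second=float(second.std(ddof=1)) if n > 1 else 0.0,
        mean_total=float(total.mean()),
        sd_total=float(total.std(ddof=1)) if n > 1 else 0.0,
        percent_longer=percent_longer(float(first.mean()),
                                      float(second.mean())),
        sufficient=n >= 2,
    )


def diurnal_compare(
    events: list[DoseEvent],
    cutoff: dt.time = DEFAULT_CUTOFF,
    test: str = "welch",
    compliance: tuple[float, float] | None = None,
    seed: int | None = None,
) -> FatigabilityReport:
    """Group completed dose events by time of day and compare their halves.

    Events starting before ``cutoff`` are "afternoon" (morning sessions fold
    in, matching the study's two-group analysis), the rest "evening".
    Comparisons: t_second between groups, t_total between groups, and
    t_first vs t_second within each group.  Incomplete events are excluded
    from the time statistics (but should be retained in the caller's
    adherence denominators).
    """
    if test not in ("welch", "permutation"):
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed) if test == "permutation" else None
    completed = [e for e in events if e.completed]
    halves = {"afternoon": ([], []), "evening": ([], [])}
    for e in completed:
        grp = "afternoon" if e.start_clock_time < cutoff else "evening"
        t1, t2 = split_half_times(e)
        halves[grp][0].append(t1)
        halves[grp][1].append(t2)
    aft1, aft2 = (np.array(v) for v in halves["afternoon"])
    eve1, eve2 = (np.array(v) for v in halves["evening"])

    comparisons = (
        _two_sample(aft2, eve2, "t_second afternoon vs evening", test, rng),
        _two_sample(aft1 + aft2, eve1 + eve2,
                    "t_total afternoon vs evening", test, rng),
        _two_sample(aft1, aft2, "afternoon t_first vs t_second", test, rng),
        _two_sample(eve1, eve2, "evening t_first vs t_second", test, rng),
    )
    return FatigabilityReport(
        afternoon=_group_stats("afternoon", aft1, aft2),
        evening=_group_stats("evening", eve1, eve2),
        comparisons=comparisons,
        cutoff=cutoff,
        test=test,
        n_events_total=len(events),
        n_excluded_incomplete=len(events) - len(completed),
        compliance_days_per_week=compliance,
    )


def compliance_summary(
    events: list[DoseEvent], weeks: float
) -> tuple[float, float]:
    """Mean (SD) notification-days per week across participants.

    Counts, per participant, the distinct calendar days with at least one
    notification, divides by ``weeks``, then aggregates.  Incomplete events
    carry no notification and therefore do not count.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    days: dict[str, set[dt.date]] = {}
    for e in events:
        days.setdefault(e.participant_id, set())
        if e.completed:
            days[e.participant_id].add(e.date)
    if not days:
        return 0.0, 0.0
    per = np.array([len(v) / weeks for v in days.values()], dtype=float)
    sd = float(per.std(ddof=1)) if per.size > 1 else 0.0
    return float(per.mean()), sd
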
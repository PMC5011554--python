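"""Bout-phase segmentation and joint (LWO, HR) fatigue detection.

A high-sensitivity Δt° recording of an exercise bout decomposes into four
phases: (1) rise toward the thermal steady state, (2) plateau at steady work
output, (3) progressive decline while exercise continues (the work-output
signature of muscle fatigue), and (4) post-cessation recovery.  Fatigue onset
during a bout is defined on the joint behaviour of the two signals: either
the work output (LWO, recovered from Δt° by the inverse thermal model)
declines while heart rate stays steady, or heart rate climbs while the work
output stays steady.  A bout with both signals steady for the whole exercise
portion is fatigue-free.

Onset reporting: a steadiness violation is *confirmed* at the first sample
where the deviation exceeds its tolerance for ``persistence`` consecutive
minutes, but the confirmed sample necessarily lags the true inflection (the
signal must first drift across the tolerance band).  The reported
``onset_minute`` is therefore the start of the sustained deviation run: the
breakpoint of a two-segment (constant → linear-trend) least-squares fit,
constrained to precede the confirmed violation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import theilslopes

from .cohort import TrainingBout
from .device import DeviceParams, Mode, SensorTrace, estimate_power

__all__ = [
    "PhaseSegmentation",
    "FatigueAssessment",
    "FatigueCriteria",
    "SegmentationError",
    "segment_phases",
    "detect_fatigue",
    "two_segment_breakpoint",
    "default_slope_tol",
    "default_smooth_window",
]

PHASES = ("rise", "plateau", "decline", "recovery")


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSegmentation:
    """Phase boundaries of one bout, minutes at 1-min resolution.

    ``t1`` end of rise, ``t2`` end of plateau, ``t3`` end of decline (=
    exercise end), ``t4`` end of recorded recovery.  A phase may be empty
    (t1=t2 or t2=t3).  ``labels`` assigns one of rise/plateau/decline/
    recovery to every sample.
    """

    t1: float
    t2: float
    t3: float
    t4: float
    labels: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.t1 <= self.t2 <= self.t3 <= self.t4):
            raise ValueError(
                f"phase boundaries must be ordered: {self.t1}, {self.t2}, "
                f"{self.t3}, {self.t4}"
            )

    def phase_slice(self, name: str) -> slice:
        bounds = {
            "rise": (0.0, self.t1),
            "plateau": (self.t1, self.t2),
            "decline": (self.t2, self.t3),
            "recovery": (self.t3, self.t4),
        }[name]
        return slice(int(bounds[0]), int(bounds[1]) + 1)


@dataclass(frozen=True)
class FatigueAssessment:
    """Outcome of the joint LWO/HR fatigue criterion for one bout."""

    fatigue_free: bool
    onset_minute: float | None
    mechanism: str  # lwo_decline_steady_hr | hr_rise_steady_lwo | none
    hr_steady: bool
    lwo_steady: bool
    partial: bool = False  # HR trace missing; only the LWO mechanism assessed

    def __post_init__(self) -> None:
        none_like = self.mechanism == "none"
        if not (self.fatigue_free == none_like == (self.onset_minute is None)):
            raise ValueError(
                "fatigue_free, mechanism='none' and absent onset_minute must "
                "agree"
            )


@dataclass(frozen=True)
class FatigueCriteria:
    """Tolerances of the steadiness definitions.

    hr_drift_tol: maximal robust-fit HR drift over the exercise portion, BPM.
    lwo_drop_tol: fractional drop of estimated power below its plateau median
        that counts as a violation.
    persistence: minutes a violation must persist to be confirmed.
    smooth_window: width (minutes) of the derivative filter feeding the
        work-rate estimate; ``None`` selects the mode default — 3 min in high
        sensitivity, 7 min in low sensitivity, where the shallow slope makes
        the deconvolved signal far noisier per sample.
    tie_rule: when both mechanisms are violated — ``z_score`` picks the signal
        deviating by more standard scores, ``earliest`` the earlier onset.
    """

    hr_drift_tol: float = 15.0
    lwo_drop_tol: float = 0.10
    persistence: int = 3
    smooth_window: float | None = None
    tie_rule: str = "z_score"


def default_slope_tol(mode: Mode) -> float:
    """Slope tolerance (°C/min) separating rise/plateau/decline by mode."""
    return 0.5 if Mode(mode) is Mode.HIGH else 0.05


def default_smooth_window(mode: Mode) -> float:
    """Mode default for the work-rate smoothing window (minutes)."""
    return 3.0 if Mode(mode) is Mode.HIGH else 7.0


def _smoothed_slope(delta_t: np.ndarray, smooth_window: float) -> np.ndarray:
    window = int(round(smooth_window))
    if window % 2 == 0:
        window += 1
    window = max(window, 3)
    window = min(window, delta_t.size if delta_t.size % 2 else delta_t.size - 1)
    return savgol_filter(delta_t, window, polyorder=1, deriv=1, delta=1.0)


def segment_phases(
    trace: SensorTrace,
    smooth_window: float = 3.0,
    slope_tol: float | None = None,
    exercise_end: float | None = None,
) -> PhaseSegmentation:
    """Decompose a Δt° trace into rise/plateau/decline/recovery phases.

    Phases are assigned from the smoothed slope s(τ): rise while
    s > +slope_tol, plateau while |s| ≤ slope_tol, decline while
    s < −slope_tol during exercise; everything after ``exercise_end`` is
    recovery.  When the bout metadata does not supply ``exercise_end``, it is
    detected as the steepest sustained negative change of slope (cessation
    makes the heating term vanish abruptly); a trace that never rises above
    the tolerance is returned flagged ``degenerate``.
    """
    if len(trace) < 5:
        raise SegmentationError(
            f"trace of {len(trace)} samples is shorter than the 5-minute "
            "minimum for phase segmentation"
        )
    if slope_tol is None:
        slope_tol = default_slope_tol(trace.mode)
    s = _smoothed_slope(trace.delta_t, smooth_window)
    n = len(trace)
    end_time = float(trace.times[-1])

    if exercise_end is None:
        ds = np.diff(s)
        k = int(np.argmin(ds))
        # a genuine cessation shows a sustained slope drop followed by a
        # falling trace; otherwise the whole record is exercise
        if (
            ds[k] < -2.0 * slope_tol
            and 2 <= k <= n - 3
            and float(np.mean(s[k + 1 :])) < -slope_tol
        ):
            exercise_end = float(trace.times[k])
        else:
            exercise_end = end_time
    exercise_end = min(exercise_end, end_time)
    ex = int(round(exercise_end))

    rising = s > slope_tol
    if not rising[: max(ex, 1)].any():
        labels = np.array(["plateau"] * n, dtype=object)
        labels[ex + 1 :] = "recovery"
        return PhaseSegmentation(
            t1=float(max(ex, 1)), t2=float(ex), t3=float(ex),
            t4=end_time, labels=labels, degenerate=True,
        )

    # end of rise: first sample after which the slope stays <= tol
    above = np.nonzero(rising[: ex + 1])[0]
    first_non_rise = above[0]
    t1 = first_non_rise
    while t1 + 1 <= ex and s[t1 + 1] > slope_tol:
        t1 += 1
    t1 = min(t1 + 1, ex)

    declining = s < -slope_tol
    decl = np.nonzero(declining[t1 : ex + 1])[0]
    t2 = int(t1 + decl[0]) if decl.size else ex
    t3 = ex

    labels = np.empty(n, dtype=object)
    idx = trace.times
    labels[idx <= t1] = "rise"
    labels[(idx > t1) & (idx <= t2)] = "plateau"
    labels[(idx > t2) & (idx <= t3)] = "decline"
    labels[idx > t3] = "recovery"
    return PhaseSegmentation(
        t1=float(t1), t2=float(t2), t3=float(t3), t4=end_time, labels=labels
    )


def two_segment_breakpoint(y: np.ndarray, b_max: int | None = None) -> int:
    """Least-squares breakpoint of a constant→linear two-segment model.

    Scans every candidate breakpoint b, fitting a constant to ``y[:b+1]`` and
    a straight line to ``y[b:]``, and returns the b minimising the combined
    squared error.  ``b_max`` restricts the scan (e.g. to samples preceding a
    confirmed violation).  Exhaustive O(n²), adequate for minute-gridded
    bouts.
    """
    n = y.size
    if n < 4:
        return 0
    hi = n - 3 if b_max is None else min(b_max, n - 3)
    hi = max(hi, 1)
    best_b, best_sse = 1, np.inf
    x = np.arange(n, dtype=float)
    for b in range(1, hi + 1):
        head = y[: b + 1]
        sse = float(np.sum((head - head.mean()) ** 2))
        xt, yt = x[b:], y[b:]
        A = np.vstack([xt, np.ones_like(xt)]).T
        coef, res, *_ = np.linalg.lstsq(A, yt, rcond=None)
        sse += float(res[0]) if res.size else float(
            np.sum((yt - A @ coef) ** 2)
        )
        if sse < best_sse:
            best_sse, best_b = sse, b
    return best_b


def _sustained_violation(mask: np.ndarray, persistence: int) -> int | None:
    """First index opening a run of >= persistence consecutive True values."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def detect_fatigue(
    bout: TrainingBout,
    device: DeviceParams,
    criteria: FatigueCriteria | None = None,
) -> FatigueAssessment:
    """Assess a bout against the joint LWO/HR fatigue criterion.

    HR is steady iff a Theil–Sen robust fit over the exercise portion drifts
    by at most ``hr_drift_tol`` BPM in total.  LWO is steady iff the
    estimated work rate never stays below (1 − lwo_drop_tol) × its plateau
    median for ``persistence`` consecutive minutes.  The onset is the
    two-segment breakpoint of the violated signal (see module docstring);
    when both signals are violated the tie rule picks the mechanism.
    """
    criteria = criteria or FatigueCriteria()
    smooth = criteria.smooth_window or default_smooth_window(device.mode)
    ex_mask = bout.sensor.times <= bout.exercise_end
    if ex_mask.sum() < 10:
        raise SegmentationError("exercise portion must cover >= 10 minutes")
    times = bout.sensor.times[ex_mask]

    # --- LWO steadiness on the deconvolved work-rate signal.  The first
    # samples of the estimate are edge-distorted (forced Δ(0)=0 plus the
    # smoothing filter's boundary), so the scan starts past the filter edge.
    p_all = estimate_power(bout.sensor, device, smooth).power[ex_mask]
    w = int(smooth) // 2 + 1
    p_hat = p_all[w:]
    interior = p_hat[:-w] if p_hat.size > w + 2 else p_hat
    ref = float(np.median(interior))
    lwo_mask = p_hat < (1.0 - criteria.lwo_drop_tol) * ref
    lwo_viol = _sustained_violation(lwo_mask, criteria.persistence)
    lwo_steady = lwo_viol is None
    lwo_onset = None
    if not lwo_steady:
        b = two_segment_breakpoint(p_hat, b_max=lwo_viol)
        lwo_onset = float(times[w + b])

    # --- HR steadiness via robust drift
    hr_steady, hr_onset, hr_drift = True, None, 0.0
    partial = bout.hr is None
    if not partial:
        bpm = bout.hr.bpm[ex_mask]
        slope = theilslopes(bpm, times)[0]
        hr_drift = slope * (times[-1] - times[0])
        if abs(hr_drift) > criteria.hr_drift_tol and hr_drift > 0:
            hr_steady = False
            hr_viol = None
            # confirm where smoothed HR leaves its early band, then backdate
            level = np.median(bpm[: max(5, criteria.persistence)])
            hr_mask = bpm > level + criteria.hr_drift_tol
            hr_viol = _sustained_violation(hr_mask, criteria.persistence)
            b = two_segment_breakpoint(bpm, b_max=hr_viol)
            hr_onset = float(times[b])

    if lwo_steady and hr_steady:
        return FatigueAssessment(
            fatigue_free=True, onset_minute=None, mechanism="none",
            hr_steady=True, lwo_steady=True, partial=partial,
        )

    if not lwo_steady and not hr_steady:
        if criteria.tie_rule == "earliest":
            pick_lwo = lwo_onset <= hr_onset
        else:  # z_score: signal deviating by more standard scores wins
            z_lwo = (ref - float(p_hat.min())) / (float(np.std(interior)) + 1e-9)
            bpm = bout.hr.bpm[ex_mask]
            z_hr = hr_drift / (float(np.std(bpm[:10])) + 1e-9)
            pick_lwo = z_lwo >= z_hr
    else:
        pick_lwo = not lwo_steady

    if pick_lwo:
        mechanism, onset = "lwo_decline_steady_hr", lwo_onset
    else:
        mechanism, onset = "hr_rise_steady_lwo", hr_onset
    return FatigueAssessment(
        fatigue_free=False, onset_minute=onset, mechanism=mechanism,
        hr_steady=hr_steady, lwo_steady=lwo_steady, partial=partial,
    )
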
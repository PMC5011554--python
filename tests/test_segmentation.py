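"""Phase segmentation and fatigue detection against planted ground truth."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from legwork.cohort import Participant, Regimen, simulate_bout
from legwork.device import HIGH_SENSITIVITY, LOW_SENSITIVITY, SensorTrace, estimate_power
from legwork.segmentation import (
    FatigueCriteria,
    SegmentationError,
    default_smooth_window,
    detect_fatigue,
    segment_phases,
    two_segment_breakpoint,
)

from conftest import SEED, constant_power_trace


class TestSegmentPhases:
    def test_constant_power_has_empty_decline(self):
        tr = constant_power_trace(1.0, 30, HIGH_SENSITIVITY)
        seg = segment_phases(tr, exercise_end=30.0)
        assert seg.t2 == seg.t3 == 30.0
        assert 6 <= seg.t1 <= 11  # thermal rise ends once the slope flattens
        plateau = tr.delta_t[seg.phase_slice("plateau")]
        assert np.median(plateau) == pytest.approx(34.2, rel=0.02)

    def test_vigorous_bout_shows_decline_phase(self, vigorous_bout):
        seg = segment_phases(
            vigorous_bout.sensor, exercise_end=vigorous_bout.exercise_end
        )
        # the planted work-rate decline at 7 min surfaces in the temperature
        # trace a few minutes later (thermal lag plus the slope-tolerance
        # band): the plateau must end shortly after the latent onset, and a
        # decline phase must occupy the rest of the exercise portion
        assert vigorous_bout.planted_onset <= seg.t2 <= vigorous_bout.planted_onset + 5
        assert seg.t3 == 30.0
        assert (seg.labels == "decline").sum() >= 15
        # the latent onset itself is the fatigue detector's job
        a = detect_fatigue(vigorous_bout, HIGH_SENSITIVITY)
        assert a.onset_minute == pytest.approx(
            vigorous_bout.planted_onset, abs=2.0
        )

    def test_fatigue_free_mict_has_no_decline(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=100.0, duration=30.0),
            HIGH_SENSITIVITY, seed=SEED,
        )
        seg = segment_phases(bout.sensor, exercise_end=30.0)
        assert seg.t2 == seg.t3 == 30.0

    def test_recovery_detected_without_metadata(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=120.0, duration=20.0),
            HIGH_SENSITIVITY, seed=3, recovery_min=10.0,
        )
        seg = segment_phases(bout.sensor)  # exercise end inferred
        assert seg.t3 == pytest.approx(20.0, abs=2.0)
        assert seg.t4 == 30.0
        assert (seg.labels == "recovery").sum() >= 8

    def test_short_trace_rejected(self):
        tr = SensorTrace(np.arange(4.0), np.array([0.0, 1.0, 2.0, 3.0]))
        with pytest.raises(SegmentationError, match="5-minute"):
            segment_phases(tr)

    def test_all_noise_trace_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        tr = SensorTrace(np.arange(31.0), np.abs(rng.normal(0, 0.05, 31)) * 0)
        seg = segment_phases(tr, exercise_end=30.0)
        assert seg.degenerate


class TestDetectFatigue:
    def test_fatigue_free_by_construction(self, fatigue_free_bout):
        a = detect_fatigue(fatigue_free_bout, LOW_SENSITIVITY)
        assert a.fatigue_free
        assert a.mechanism == "none"
        assert a.onset_minute is None

    def test_lwo_decline_at_moderate_vigorous(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=120.0, duration=30.0),
            HIGH_SENSITIVITY, seed=SEED,
        )
        a = detect_fatigue(bout, HIGH_SENSITIVITY)
        assert a.mechanism == "lwo_decline_steady_hr"
        assert a.onset_minute == pytest.approx(15.0, abs=2.0)
        assert a.hr_steady

    def test_hr_rise_at_constant_power(self, mean_participant):
        """Mean onset error over seeded constant-power bouts stays within 2
        minutes of the planted HR-rise onset."""
        errors = []
        for s in range(10):
            bout = simulate_bout(
                mean_participant,
                Regimen(control="hold_power", target=1.0, duration=30.0),
                HIGH_SENSITIVITY, seed=100 + s,
            )
            a = detect_fatigue(bout, HIGH_SENSITIVITY)
            assert a.mechanism == "hr_rise_steady_lwo"
            assert a.lwo_steady
            errors.append(a.onset_minute - bout.planted_onset)
        assert abs(np.mean(errors)) <= 2.0

    def test_onset_recovery_within_two_minutes(self, mean_participant):
        """50-replicate parameter recovery: the detector finds the planted
        work-rate decline within ±2 min at default sensor noise."""
        reg = Regimen(control="hold_hr", target=130.0, duration=30.0)
        for s in range(50):
            bout = simulate_bout(
                mean_participant, reg, HIGH_SENSITIVITY, seed=2000 + s
            )
            a = detect_fatigue(bout, HIGH_SENSITIVITY)
            assert a.mechanism == "lwo_decline_steady_hr"
            assert a.onset_minute == pytest.approx(bout.planted_onset, abs=2.0)

    def test_exactly_one_mechanism_and_onset_inside_exercise(self, mean_participant):
        for hr, s in ((130.0, 1), (120.0, 2), (100.0, 3)):
            bout = simulate_bout(
                mean_participant,
                Regimen(control="hold_hr", target=hr, duration=30.0),
                HIGH_SENSITIVITY, seed=s,
            )
            a = detect_fatigue(bout, HIGH_SENSITIVITY)
            assert a.mechanism in (
                "none", "lwo_decline_steady_hr", "hr_rise_steady_lwo"
            )
            if a.onset_minute is not None:
                assert 0 <= a.onset_minute <= bout.exercise_end

    def test_monotone_sensitivity_in_drop_tolerance(self, vigorous_bout):
        """Decreasing lwo_drop_tol never moves the reported onset later."""
        onsets = []
        for tol in (0.20, 0.15, 0.10, 0.05):
            a = detect_fatigue(
                vigorous_bout, HIGH_SENSITIVITY,
                FatigueCriteria(lwo_drop_tol=tol),
            )
            onsets.append(np.inf if a.onset_minute is None else a.onset_minute)
        assert all(b <= a for a, b in zip(onsets, onsets[1:]))

    def test_brute_force_oracle_equivalence(self, mean_participant):
        """On noise-free traces the vectorised detector agrees with a plain
        loop implementing the documented definition sample by sample."""
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=120.0, duration=30.0),
            HIGH_SENSITIVITY, seed=5, noise_sd=0.0,
        )
        crit = FatigueCriteria()
        a = detect_fatigue(bout, HIGH_SENSITIVITY, crit)

        # oracle: exhaustive scan, no vectorisation
        smooth = default_smooth_window(HIGH_SENSITIVITY.mode)
        p_all = estimate_power(bout.sensor, HIGH_SENSITIVITY, smooth).power
        w = int(smooth) // 2 + 1
        p_hat = p_all[w:]
        interior = p_hat[:-w]
        ref = float(np.median(interior))
        viol = None
        for k in range(len(p_hat) - crit.persistence + 1):
            if all(
                p_hat[k + j] < (1 - crit.lwo_drop_tol) * ref
                for j in range(crit.persistence)
            ):
                viol = k
                break
        assert viol is not None
        # exhaustive two-segment fit up to the violation
        best_b, best_sse = None, np.inf
        x = np.arange(len(p_hat), dtype=float)
        for b in range(1, min(viol, len(p_hat) - 3) + 1):
            head = p_hat[: b + 1]
            sse = sum((v - head.mean()) ** 2 for v in head)
            coef = np.polyfit(x[b:], p_hat[b:], 1)
            sse += sum((p_hat[b:] - np.polyval(coef, x[b:])) ** 2)
            if sse < best_sse:
                best_sse, best_b = sse, b
        expected_onset = bout.sensor.times[w + best_b]
        assert a.onset_minute == pytest.approx(expected_onset, abs=1e-9)

    def test_missing_hr_gives_partial_assessment(self, fatigue_free_bout):
        bout = dataclasses.replace(fatigue_free_bout, hr=None)
        a = detect_fatigue(bout, LOW_SENSITIVITY)
        assert a.partial
        assert a.fatigue_free  # LWO steady; HR unassessable

    def test_short_exercise_portion_rejected(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=100.0, duration=8.0),
            HIGH_SENSITIVITY, seed=1,
        )
        with pytest.raises(SegmentationError, match="10 minutes"):
            detect_fatigue(bout, HIGH_SENSITIVITY)


class TestInverseIntensityEndurance:
    def test_steady_state_duration_ordering(self):
        """Across the default cohort, detected steady-output duration is
        shortest at HR 130 and longest (unbounded) at HR 100."""
        cohort = [Participant(id=f"p{i}") for i in range(3)]
        for i, p in enumerate(cohort):
            onsets = {}
            for hr in (130.0, 120.0, 100.0):
                bout = simulate_bout(
                    p, Regimen(control="hold_hr", target=hr, duration=30.0),
                    HIGH_SENSITIVITY, seed=50 + i,
                )
                a = detect_fatigue(bout, HIGH_SENSITIVITY)
                onsets[hr] = (
                    a.onset_minute if a.onset_minute is not None else np.inf
                )
            assert onsets[130.0] < onsets[120.0] < onsets[100.0]


class TestBreakpoint:
    def test_recovers_planted_kink(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([np.full(12, 2.0), 2.0 - 0.05 * np.arange(18)])
        y += rng.normal(0, 0.01, y.size)
        assert two_segment_breakpoint(y) == pytest.approx(12, abs=1)

    def test_respects_upper_bound(self):
        y = np.concatenate([np.full(12, 2.0), 2.0 - 0.05 * np.arange(18)])
        assert two_segment_breakpoint(y, b_max=8) <= 8
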
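"""Synthetic generator: cohort draws, bout simulation, programs, RPE bands."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from legwork.cohort import (
    HOME_PARTICIPANT,
    Participant,
    ProgramSchedule,
    Regimen,
    SessionWindow,
    intensity_map,
    make_cohort,
    rpe_category,
    simulate_bout,
    simulate_program,
)
from legwork.device import HIGH_SENSITIVITY, LOW_SENSITIVITY
from legwork.dosimetry import split_sessions

from conftest import SEED


class TestRpeBanding:
    @pytest.mark.parametrize(
        "score, band",
        [(6, "light"), (11, "light"), (12, "moderate"), (13, "moderate"),
         (14, "moderate"), (15, "strenuous"), (20, "strenuous")],
    )
    def test_borg_bands(self, score, band):
        assert rpe_category(score) == band

    @pytest.mark.parametrize("score", [5, 21, 0])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            rpe_category(score)


class TestIntensityMap:
    def test_anchor_points(self):
        assert intensity_map(100) == 1.0
        assert intensity_map(120) == 1.5
        assert intensity_map(130) == 1.8

    def test_monotone_between_anchors(self):
        hrs = np.linspace(80, 150, 50)
        vals = [intensity_map(h) for h in hrs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestMakeCohort:
    def test_degenerate_distribution(self):
        (p,) = make_cohort(1, variability_cv=0.0, seed=0)
        assert p.power_scale == 1.0

    def test_seed_reproducibility_and_truncation(self):
        a = make_cohort(30, 0.17, seed=5)
        b = make_cohort(30, 0.17, seed=5)
        assert [p.power_scale for p in a] == [p.power_scale for p in b]
        assert all(p.power_scale > 0.5 for p in a)
        assert all(25 <= p.age <= 52 for p in a)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(0)

    def test_dose_cv_matches_cohort_cv(self):
        """Monte-Carlo: through the near-linear low-mode dose map, the
        empirical CV of the 30-min dose tracks the cohort work-rate CV."""
        cohort = make_cohort(10000, 0.17, seed=11)
        doses = 8.1 * np.array([p.power_scale for p in cohort])
        cv = doses.std() / doses.mean()
        assert cv == pytest.approx(0.17, abs=0.01)


class TestSimulateBout:
    def test_moderate_bout_is_fatigue_free_by_construction(self, fatigue_free_bout):
        assert fatigue_free_bout.planted_onset is None
        assert fatigue_free_bout.hr.bpm.mean() == pytest.approx(100, abs=5)

    @pytest.mark.parametrize("hr, onset", [(130.0, 7.0), (120.0, 15.0)])
    def test_planted_onset_follows_the_linear_law(self, hr, onset, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=hr, duration=30.0),
            HIGH_SENSITIVITY, seed=2,
        )
        assert bout.planted_onset == pytest.approx(onset)
        assert bout.planted_mechanism == "lwo_decline_steady_hr"

    def test_evening_advances_onset(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_hr", target=120.0, duration=30.0),
            HIGH_SENSITIVITY, clock_time=dt.time(19, 0), seed=2,
        )
        assert bout.is_evening
        assert bout.planted_onset == pytest.approx(
            15.0 / mean_participant.evening_factor
        )

    def test_hold_power_bout_drifts_hr_toward_max(self, mean_participant):
        bout = simulate_bout(
            mean_participant,
            Regimen(control="hold_power", target=1.0, duration=30.0),
            HIGH_SENSITIVITY, seed=4,
        )
        assert bout.planted_mechanism == "hr_rise_steady_lwo"
        early = bout.hr.bpm[:8].mean()
        late = bout.hr.bpm[-8:].mean()
        assert early == pytest.approx(100, abs=8)
        assert late - early > 15  # rises toward ~130 as in the variable bout

    def test_dose_reached_stops_one_sample_after_crossing(self):
        p = dataclasses.replace(HOME_PARTICIPANT, day_cv=0.0, pace_drift_sd=0.0)
        reg = Regimen(control="hold_hr", target=100.0, duration=0.0,
                      stop_rule="dose_reached", dose_threshold=10.0)
        bout = simulate_bout(p, reg, LOW_SENSITIVITY, seed=3, noise_sd=0.0)
        d = bout.sensor.delta_t
        assert d[-2] >= 10.0 and np.all(d[:-2] < 10.0)
        assert not bout.timed_out

    def test_unreachable_dose_flags_timeout(self, mean_participant):
        reg = Regimen(control="hold_hr", target=100.0, duration=0.0,
                      stop_rule="dose_reached", dose_threshold=60.0)
        bout = simulate_bout(mean_participant, reg, LOW_SENSITIVITY, seed=3)
        assert bout.timed_out
        assert bout.sensor.times[-1] == 120.0

    def test_dose_proportional_to_duration_without_fatigue(self, mean_participant):
        """Fatigue-free low-mode doses at 15/30/60 min stand in the printed
        0.5/1.0/2.0 ratio within 8%."""
        p = dataclasses.replace(
            mean_participant, day_cv=0.0, pace_drift_sd=0.0, decay_cv=0.0,
            fatigue_onset_ref=999.0,  # fatigue disabled: onset beyond any bout
        )
        doses = {}
        for minutes in (15, 30, 60):
            reg = Regimen(control="hold_hr", target=100.0, duration=minutes)
            bout = simulate_bout(p, reg, LOW_SENSITIVITY, seed=6, noise_sd=0.0)
            doses[minutes] = bout.sensor.delta_t[-1]
        assert doses[15] / doses[30] == pytest.approx(0.5, rel=0.08)
        assert doses[60] / doses[30] == pytest.approx(2.0, rel=0.08)

    def test_bit_for_bit_determinism_at_csv_precision(self, mean_participant,
                                                      mict_regimen):
        a = simulate_bout(mean_participant, mict_regimen, LOW_SENSITIVITY, seed=9)
        b = simulate_bout(mean_participant, mict_regimen, LOW_SENSITIVITY, seed=9)
        np.testing.assert_array_equal(
            np.round(a.sensor.delta_t, 3), np.round(b.sensor.delta_t, 3)
        )
        np.testing.assert_array_equal(a.hr.bpm, b.hr.bpm)

    def test_diurnal_effect_lengthens_second_half(self):
        """Across >=100 bouts per group, the evening second-half/first-half
        time ratio strictly exceeds the afternoon ratio (default calibration)."""
        from legwork.dosimetry import DosePrescription, track_dose

        rx = DosePrescription(participant_id="x", threshold_c=10.0)
        reg = Regimen(control="hold_hr", target=100.0, duration=0.0,
                      stop_rule="dose_reached", dose_threshold=10.0)
        ratios = {}
        for name, clock in (("afternoon", dt.time(14, 0)),
                            ("evening", dt.time(19, 0))):
            firsts, seconds = [], []
            for i in range(100):
                bout = simulate_bout(
                    HOME_PARTICIPANT, reg, LOW_SENSITIVITY,
                    clock_time=clock, seed=1000 + i,
                )
                ev = track_dose(bout.sensor, rx, clock)
                firsts.append(ev.t_half)
                seconds.append(ev.t_full - ev.t_half)
            ratios[name] = np.mean(seconds) / np.mean(firsts)
        assert ratios["evening"] > ratios["afternoon"]

    def test_recovery_tail_appended(self, mean_participant):
        reg = Regimen(control="hold_hr", target=120.0, duration=20.0)
        bout = simulate_bout(
            mean_participant, reg, HIGH_SENSITIVITY, seed=3, recovery_min=8.0
        )
        assert bout.exercise_end == 20.0
        assert bout.sensor.times[-1] == 28.0
        # temperature falls and HR relaxes toward rest after cessation
        assert bout.sensor.delta_t[-1] < bout.sensor.delta_t[20]
        assert bout.hr.bpm[-1] < bout.hr.bpm[:20].mean()


class TestSimulateProgram:
    def test_printed_15_day_schedule(self):
        sched = ProgramSchedule(
            weeks=1, n_days=15, skip_days=frozenset({4, 10, 13, 14}), seed=SEED
        )
        reg = Regimen(control="hold_hr", target=100.0, duration=0.0,
                      stop_rule="dose_reached", dose_threshold=10.0)
        result = simulate_program(HOME_PARTICIPANT, sched, reg, LOW_SENSITIVITY)
        assert len(result.bouts) == 11
        skipped = [(d - sched.start_date).days + 1 for d in result.skipped_days]
        assert skipped == [4, 10, 13, 14]
        # the continuous recording separates back into 11 zeroed sessions
        sessions = split_sessions(result.trace_minutes, result.trace_delta_t)
        assert len(sessions) == 11

    def test_full_adherence_trains_every_day(self, mean_participant):
        sched = ProgramSchedule(weeks=1, adherence_prob=1.0, seed=0)
        reg = Regimen(control="hold_hr", target=100.0, duration=30.0)
        result = simulate_program(mean_participant, sched, reg, LOW_SENSITIVITY)
        assert len(result.bouts) == 7

    def test_program_determinism(self, mean_participant):
        sched = ProgramSchedule(weeks=2, adherence_prob=0.6, seed=12)
        reg = Regimen(control="hold_hr", target=100.0, duration=30.0)
        r1 = simulate_program(mean_participant, sched, reg, LOW_SENSITIVITY)
        r2 = simulate_program(mean_participant, sched, reg, LOW_SENSITIVITY)
        assert r1.trained_days == r2.trained_days
        np.testing.assert_array_equal(r1.trace_delta_t, r2.trace_delta_t)

    def test_windows_control_time_of_day(self, mean_participant):
        sched = ProgramSchedule(
            weeks=1, adherence_prob=1.0, seed=3,
            session_windows=(SessionWindow(tod="evening",
                                           start=dt.time(18, 0),
                                           end=dt.time(21, 0)),),
        )
        reg = Regimen(control="hold_hr", target=100.0, duration=30.0)
        result = simulate_program(mean_participant, sched, reg, LOW_SENSITIVITY)
        assert all(b.is_evening for b in result.bouts)


class TestParticipantValidation:
    def test_hr_max_formula(self):
        assert Participant(id="a", age=52).hr_max == 168

    @pytest.mark.parametrize(
        "kwargs",
        [{"power_scale": 0.0}, {"evening_factor": 0.9},
         {"fatigue_onset_ref": 0.0}, {"hr_rest": 200, "age": 45}],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Participant(id="bad", **kwargs)
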
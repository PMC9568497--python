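import math

import numpy as np
import pytest
from reference_detector import ref_detect_microsaccades, ref_sigma, ref_velocity

from gazecue import (DegenerateTrialError, DetectorParams, GazeTrace,
                     JoinError, TraceSimConfig, apply_trial_exclusions,
                     check_fixation, compute_velocity, detect_events,
                     detect_microsaccades, detect_saccades_and_blinks,
                     estimate_threshold, simulate_trace)
from gazecue.simulate import _raised_cosine_displacement
from gazecue.types import OcularEvent, TrialRecord


def flat_trace(n=1000, x=0.0, y=0.0, trial_id="t0"):
    return GazeTrace("s", trial_id, np.arange(n, dtype=float),
                     np.full(n, x), np.full(n, y), np.ones(n, dtype=bool))


def step_trace(amplitude_deg=10.0, duration_ms=30, n=1000, onset=400):
    """Smooth ballistic step of ``amplitude_deg`` over ``duration_ms``."""
    t = np.arange(n, dtype=float)
    x = amplitude_deg * _raised_cosine_displacement(t - onset, duration_ms)
    return GazeTrace("s", "t0", t, x, np.zeros(n), np.ones(n, dtype=bool))


class TestVelocity:
    def test_constant_trace_has_zero_velocity(self):
        vx, vy, speed, accel = compute_velocity(flat_trace())
        assert np.all(vx == 0) and np.all(vy == 0)
        assert np.all(speed == 0) and np.all(accel == 0)

    def test_linear_ramp_recovers_slope_exactly(self):
        n, c = 200, 3.5  # deg/s
        t = np.arange(n, dtype=float)
        tr = GazeTrace("s", "t0", t, c * t / 1000.0, np.zeros(n),
                       np.ones(n, dtype=bool))
        vx, _, _, _ = compute_velocity(tr)
        np.testing.assert_allclose(vx, c, atol=1e-9)

    def test_matches_per_sample_reference(self, rng):
        n = 200
        t = np.arange(n, dtype=float)
        x = np.cumsum(rng.normal(0, 0.01, n))
        y = np.cumsum(rng.normal(0, 0.01, n))
        valid = np.ones(n, dtype=bool)
        valid[80:95] = False
        tr = GazeTrace("s", "t0", t, x, y, valid)
        vx, vy, speed, accel = compute_velocity(tr, 5)
        rvx, rvy, rspeed, raccel = ref_velocity(x, y, valid, 1.0, 5)
        np.testing.assert_allclose(vx, rvx, atol=1e-9)
        np.testing.assert_allclose(vy, rvy, atol=1e-9)
        np.testing.assert_allclose(speed, rspeed, atol=1e-9)
        np.testing.assert_allclose(accel, raccel, atol=1e-6)

    def test_velocity_undefined_near_missing_pupil(self):
        tr = flat_trace(100)
        tr.pupil_valid[50] = False
        vx, _, _, _ = compute_velocity(tr, 5)
        assert np.isnan(vx[48:53]).all()
        assert np.isfinite(vx[:48]).all() and np.isfinite(vx[53:]).all()


class TestThreshold:
    def test_alternating_velocities_match_brute_force_medians(self):
        vx = np.tile([1.0, -1.0], 50)
        vy = np.tile([0.5, -0.5], 50)
        eta_x, eta_y = estimate_threshold(vx, vy, 6.0)
        assert eta_x == pytest.approx(6.0 * ref_sigma(list(vx)))
        assert eta_y == pytest.approx(6.0 * ref_sigma(list(vy)))

    def test_constant_velocity_is_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            estimate_threshold(np.ones(50), np.ones(50))

    def test_threshold_scales_with_velocity(self, rng):
        vx = rng.normal(0, 2, 500)
        vy = rng.normal(0, 2, 500)
        e1 = estimate_threshold(vx, vy)
        e3 = estimate_threshold(3 * vx, 3 * vy)
        assert e3[0] == pytest.approx(3 * e1[0])
        assert e3[1] == pytest.approx(3 * e1[1])


class TestMicrosaccadeDetection:
    def test_constant_trace_yields_no_events(self, caplog):
        with caplog.at_level("WARNING"):
            assert detect_microsaccades(flat_trace()) == []

    def test_single_injected_event_recovered(self, zero_jitter_timeline):
        rng = np.random.default_rng(3)
        cfg = TraceSimConfig(ms_rate_hz=0.0, blink_prob_per_trial=0.0)
        trace, _ = simulate_trace(cfg, zero_jitter_timeline, "right", rng=rng)
        # inject one 0.3 deg rightward event of ~22 ms by hand
        onset, dur, amp = 1000.0, cfg.event_duration_ms, 0.3
        trace.x_deg += amp * _raised_cosine_displacement(trace.t_ms - onset, dur)
        events = detect_microsaccades(trace)
        assert len(events) == 1
        (ev,) = events
        assert ev.kind == "microsaccade"
        assert abs(ev.onset_ms - onset) <= 5.0
        assert ev.amplitude_deg == pytest.approx(amp, rel=0.10)
        assert ev.dx_deg > 0

    def test_equals_reference_loop_on_simulated_traces(self, simulated_batch):
        params = DetectorParams()
        for trace, _, _ in simulated_batch[:10]:
            got = detect_microsaccades(trace, params)
            want = ref_detect_microsaccades(trace, params)
            assert [(e.kind, e.onset_ms, e.offset_ms) for e in got] == [
                (kind, trace.t_ms[a], trace.t_ms[b]) for kind, a, b in want]

    def test_lambda_monotonicity(self, simulated_batch):
        for trace, _, _ in simulated_batch:
            counts = [len(detect_microsaccades(
                trace, DetectorParams(lambda_=lam))) for lam in (4, 6, 8)]
            assert counts[0] >= counts[1] >= counts[2]

    def test_events_never_overlap_after_merging(self, simulated_batch):
        params = DetectorParams()
        for trace, _, _ in simulated_batch:
            events = detect_events(trace, params)
            for a, b in zip(events, events[1:]):
                assert b.onset_ms > a.offset_ms

    def test_amplitude_cap_reclassifies_as_saccade(self, zero_jitter_timeline):
        rng = np.random.default_rng(3)
        cfg = TraceSimConfig(ms_rate_hz=0.0, blink_prob_per_trial=0.0)
        trace, _ = simulate_trace(cfg, zero_jitter_timeline, "right", rng=rng)
        trace.x_deg += 0.3 * _raised_cosine_displacement(
            trace.t_ms - 1000.0, cfg.event_duration_ms)
        params = DetectorParams(max_microsaccade_amp_deg=0.2)
        (ev,) = detect_microsaccades(trace, params)
        assert ev.kind == "saccade"


class TestSaccadesAndBlinks:
    def test_large_fast_step_is_a_saccade(self):
        events = detect_saccades_and_blinks(step_trace(10.0, 30))
        assert [e.kind for e in events] == ["saccade"]
        assert events[0].peak_velocity_deg_s > 35.0
        assert events[0].amplitude_deg == pytest.approx(10.0, rel=0.05)

    def test_missing_pupil_inside_saccade_makes_blink(self):
        tr = step_trace(10.0, 30, onset=400)
        tr.pupil_valid[410:425] = False
        events = detect_saccades_and_blinks(tr)
        assert [e.kind for e in events] == ["blink"]

    def test_slow_drift_is_not_a_saccade(self):
        n = 1000
        t = np.arange(n, dtype=float)
        tr = GazeTrace("s", "t0", t, 0.2 * t / 1000.0, np.zeros(n),
                       np.ones(n, dtype=bool))
        assert detect_saccades_and_blinks(tr) == []


class TestFixation:
    def test_small_excursion_keeps_fixation(self):
        assert check_fixation(flat_trace(x=0.5), 1.5)

    def test_break_beyond_radius(self):
        tr = flat_trace()
        tr.x_deg[500] = 1.6
        assert not check_fixation(tr, 1.5)

    def test_boundary_sample_is_kept(self):
        # the rule is "more than 1.5 deg", so exactly 1.5 is not a break
        tr = flat_trace()
        tr.x_deg[500] = 1.5
        assert check_fixation(tr, 1.5)

    def test_invalid_samples_ignored(self):
        tr = flat_trace()
        tr.x_deg[500] = 3.0
        tr.pupil_valid[500] = False
        assert check_fixation(tr, 1.5)


class TestExclusions:
    def _trial(self, i, timeline):
        return TrialRecord(
            subject_id="s1", trial_id=f"t{i:03d}", condition="intact",
            soa_ms=200, target_present=True, cue_validity="valid",
            cue_direction="left", response="present", timeline=timeline)

    def _blink(self, trial_id, onset, offset):
        return OcularEvent(trial_id=trial_id, kind="blink", onset_ms=onset,
                           offset_ms=offset, dx_deg=0.0, dy_deg=0.0,
                           amplitude_deg=0.0, direction_rad=0.0,
                           peak_velocity_deg_s=0.0)

    def test_no_blinks_no_exclusions(self, zero_jitter_timeline):
        trials = [self._trial(i, zero_jitter_timeline) for i in range(10)]
        kept, report = apply_trial_exclusions(trials, [])
        assert len(kept) == 10
        assert report["n_excluded"] == 0

    def test_blinks_during_video_excluded_with_fraction(self, zero_jitter_timeline):
        trials = [self._trial(i, zero_jitter_timeline) for i in range(100)]
        events = [self._blink("t003", 500.0, 650.0),
                  self._blink("t042", 100.0, 260.0)]
        kept, report = apply_trial_exclusions(trials, events)
        assert len(kept) == 98
        assert {t.trial_id for t in trials} - {t.trial_id for t in kept} == \
            {"t003", "t042"}
        assert report["fractions"]["blink_in_video"] == pytest.approx(0.02)

    def test_blink_after_array_offset_not_excluded(self, zero_jitter_timeline):
        end = zero_jitter_timeline.array_offset_ms
        trials = [self._trial(0, zero_jitter_timeline)]
        kept, report = apply_trial_exclusions(
            trials, [self._blink("t000", end + 10.0, end + 150.0)])
        assert len(kept) == 1 and report["n_excluded"] == 0

    def test_fixation_break_excluded(self, zero_jitter_timeline):
        trials = [self._trial(0, zero_jitter_timeline)]
        n = int(zero_jitter_timeline.array_offset_ms) + 1
        tr = GazeTrace("s1", "t000", np.arange(n, dtype=float),
                       np.full(n, 2.0), np.zeros(n), np.ones(n, dtype=bool))
        kept, report = apply_trial_exclusions(trials, [], [tr])
        assert kept == []
        assert report["counts"]["fixation_break"] == 1

    def test_unknown_trial_id_raises_join_error(self, zero_jitter_timeline):
        trials = [self._trial(0, zero_jitter_timeline)]
        with pytest.raises(JoinError, match="t999"):
            apply_trial_exclusions(trials, [self._blink("t999", 0.0, 10.0)])
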
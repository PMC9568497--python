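import math

import numpy as np
import pandas as pd
import pytest

from gazecue import (TimelineJitter, TraceSimConfig, ValidationError,
                     align_events, amplitude_summary, direction_density_map,
                     make_timeline, rate_curve, toward_cue_window_stats)
from gazecue.metrics import trial_bias_table
from gazecue.types import OcularEvent, TrialRecord, TrialTimeline


def timeline(soa=200):
    return make_timeline(soa, TimelineJitter(0.0), np.random.default_rng(0))


def trial(i, cue="right", subject="s1", tl=None, soa=200, validity="valid"):
    return TrialRecord(
        subject_id=subject, trial_id=f"t{i:03d}", condition="intact",
        soa_ms=soa, target_present=True, cue_validity=validity,
        cue_direction=cue, response="present", timeline=tl or timeline(soa))


def event(trial_id, onset, dx, dy=0.0, kind="microsaccade"):
    return OcularEvent.from_displacement(trial_id, kind, onset, onset + 20.0,
                                         dx, dy, 25.0)


class TestAlign:
    def test_video_onset_is_identity(self):
        trials = [trial(0)]
        aligned = align_events([event("t000", 123.0, 0.1)], trials,
                               "video_onset")
        assert aligned["onset_rel_ms"].iloc[0] == 123.0

    def test_array_onset_offsets_by_anchor(self):
        tl = timeline(200)  # array onset at 2000 ms
        aligned = align_events([event("t000", 2200.0, 0.1)], [trial(0, tl=tl)],
                               "array_onset")
        assert aligned["onset_rel_ms"].iloc[0] == pytest.approx(200.0)

    def test_anchor_round_trip_restores_times(self):
        tl = timeline(200)
        trials = [trial(0, tl=tl)]
        ev = [event("t000", 900.0, 0.1)]
        via = align_events(ev, trials, "array_onset")
        back = via["onset_rel_ms"] + tl.array_onset_ms
        assert back.iloc[0] == pytest.approx(900.0)

    def test_missing_trial_record_is_an_error(self):
        with pytest.raises(ValidationError, match="t999"):
            align_events([event("t999", 0.0, 0.1)], [trial(0)], "video_onset")


class TestRateCurve:
    def test_no_events_zero_curve(self):
        trials = [trial(i) for i in range(5)]
        aligned = align_events([], trials, "video_onset")
        curve = rate_curve(aligned, trials, (0.0, 1000.0), bin_ms=100.0,
                          smooth_ms=0.0)
        assert np.all(curve.rate_hz == 0.0)

    def test_single_event_single_trial_rate(self):
        # 1 onset / (1 trial x 0.1 s bin) = 10 Hz in that bin
        trials = [trial(0)]
        aligned = align_events([event("t000", 250.0, 0.1)], trials,
                               "video_onset")
        curve = rate_curve(aligned, trials, (0.0, 1000.0), bin_ms=100.0,
                          smooth_ms=0.0)
        assert curve.rate_hz[2] == pytest.approx(10.0)
        assert np.all(np.delete(curve.rate_hz, 2) == 0.0)

    def test_homogeneous_poisson_rate_recovered(self):
        rng = np.random.default_rng(9)
        rate, n_trials, span = 1.5, 500, 2500.0
        trials, events = [], []
        tl = timeline(200)
        for i in range(n_trials):
            subject = f"s{i % 5}"
            t = TrialRecord(
                subject_id=subject, trial_id=f"t{i:03d}", condition="intact",
                soa_ms=200, target_present=True, cue_validity="valid",
                cue_direction="right", response="present", timeline=tl)
            trials.append(t)
            for onset in rng.uniform(0, span, rng.poisson(rate * span / 1000)):
                events.append(event(t.trial_id, onset, 0.2))
        aligned = align_events(events, trials, "video_onset")
        curve = rate_curve(aligned, trials, (0.0, span), bin_ms=100.0,
                          smooth_ms=0.0)
        se = math.sqrt(rate / (n_trials * 0.1))
        assert np.all(np.abs(curve.rate_hz - rate) < 4 * se)

    def test_smoothing_masks_edge_bins(self):
        trials = [trial(0)]
        aligned = align_events([], trials, "video_onset")
        curve = rate_curve(aligned, trials, (0.0, 1000.0), bin_ms=10.0,
                          smooth_ms=100.0)
        assert np.isnan(curve.rate_hz[:5]).all()
        assert np.isnan(curve.rate_hz[-5:]).all()
        assert np.isfinite(curve.rate_hz[5:-5]).all()


class TestTowardCue:
    def test_all_rightward_with_right_cue(self):
        trials = [trial(0, cue="right")]  # array onset at 2000 ms
        events = [event("t000", 2150.0, +0.2), event("t000", 2350.0, +0.1)]
        aligned = align_events(events, trials, "array_onset")
        (stat,) = toward_cue_window_stats(aligned, trials, 400.0, None)
        assert stat.window_start_ms == 0.0
        assert stat.mean_proportion_toward == 1.0

    def test_hand_computed_mixed_trial(self):
        # +0.2 toward, -0.1 away with a right cue: proportion 1/2,
        # signed degrees +0.2 - 0.1 = +0.1
        tl = timeline(200)
        trials = [trial(0, cue="right", tl=tl)]
        onset = tl.array_onset_ms + 450.0
        events = [event("t000", onset, +0.2), event("t000", onset + 60, -0.1)]
        aligned = align_events(events, trials, "array_onset")
        table = trial_bias_table(aligned, trials, (400.0, 800.0))
        assert table["proportion_toward"].iloc[0] == pytest.approx(0.5)
        assert table["signed_deg_toward"].iloc[0] == pytest.approx(0.1)

    def test_left_cue_mirrors_sign(self):
        tl = timeline(200)
        trials = [trial(0, cue="left", tl=tl)]
        events = [event("t000", tl.array_onset_ms + 500.0, -0.3)]
        aligned = align_events(events, trials, "array_onset")
        table = trial_bias_table(aligned, trials, (400.0, 800.0))
        assert table["proportion_toward"].iloc[0] == 1.0
        assert table["signed_deg_toward"].iloc[0] == pytest.approx(0.3)

    def test_zero_dx_counts_as_neither(self):
        tl = timeline(200)
        trials = [trial(0, cue="right", tl=tl)]
        events = [event("t000", tl.array_onset_ms + 500.0, 0.0, dy=0.2),
                  event("t000", tl.array_onset_ms + 600.0, 0.1)]
        aligned = align_events(events, trials, "array_onset")
        table = trial_bias_table(aligned, trials, (400.0, 800.0))
        row = table.iloc[0]
        assert row["n_zero"] == 1 and row["n_events"] == 2
        assert row["proportion_toward"] == 1.0  # zero-dx excluded

    def test_conservation_in_every_window(self, simulated_batch):
        trials, events = [], []
        for i, (trace, truth, tl) in enumerate(simulated_batch):
            t = trial(i, cue="right", tl=tl, soa=500)
            trials.append(t)
            events.extend(OcularEvent(**{**e.__dict__, "trial_id": t.trial_id})
                          for e in truth)
        aligned = align_events(events, trials, "video_onset")
        stats = toward_cue_window_stats(aligned, trials, 400.0,
                                        (0.0, 2800.0), 200.0)
        assert len(stats) > 5
        for s in stats:
            assert s.n_toward + s.n_away + s.n_zero == s.n_events

    def test_configured_bias_recovered(self):
        rng = np.random.default_rng(31)
        cfg = TraceSimConfig(toward_cue_prob=0.70, blink_prob_per_trial=0.0)
        from gazecue import simulate_trace
        trials, events = [], []
        tl = timeline(200)
        n_trials, total = 300, 0
        for i in range(n_trials):
            t = trial(i, cue="right" if i % 2 else "left", tl=tl,
                      subject=f"s{i % 10}")
            trace, truth = simulate_trace(cfg, tl, t.cue_direction, rng=rng,
                                          trial_id=t.trial_id)
            trials.append(t)
            events.extend(truth)
            total += len(truth)
        aligned = align_events(events, trials, "video_onset")
        (stat,) = toward_cue_window_stats(aligned, trials, 2800.0, None)
        pooled = stat.n_toward / (stat.n_toward + stat.n_away)
        half = 2.576 * math.sqrt(0.7 * 0.3 / (stat.n_toward + stat.n_away))
        assert abs(pooled - 0.70) < half


class TestAmplitudeSummary:
    def test_hand_computed_median_and_fraction(self):
        events = [event("t0", 100.0 * i, dx) for i, dx in
                  enumerate([0.1, 0.2, 0.3], start=1)]
        summary = amplitude_summary(events, threshold_deg=0.5)
        assert summary["median_arcmin"] == pytest.approx(12.0)
        assert summary["fraction_below_threshold"] == 1.0

    def test_threshold_is_strict(self):
        summary = amplitude_summary([event("t0", 100.0, 0.5)],
                                    threshold_deg=0.5)
        assert summary["fraction_below_threshold"] == 0.0

    def test_empty_input_flagged(self):
        summary = amplitude_summary([])
        assert summary["empty"] and summary["n_events"] == 0
        assert math.isnan(summary["median_arcmin"])


class TestDensityMap:
    def _aligned(self, events, trials):
        return align_events(events, trials, "video_onset")

    def test_single_event_lands_toward_side(self):
        trials = [trial(0, cue="right")]
        dmap = direction_density_map(
            self._aligned([event("t000", 100.0, +0.2)], trials))
        x_centers = (dmap.x_edges_deg[:-1] + dmap.x_edges_deg[1:]) / 2
        ix, iy = np.unravel_index(dmap.density.argmax(), dmap.density.shape)
        assert x_centers[ix] > 0
        assert dmap.density.sum() == pytest.approx(1.0)

    def test_left_cue_is_mirrored(self):
        right = direction_density_map(self._aligned(
            [event("t000", 100.0, +0.2)], [trial(0, cue="right")]))
        left = direction_density_map(self._aligned(
            [event("t000", 100.0, -0.2)], [trial(0, cue="left")]))
        np.testing.assert_array_equal(right.density, left.density)

    def test_global_cue_flip_invariance(self, rng):
        trials = [trial(i, cue=("right" if i % 2 else "left"))
                  for i in range(20)]
        events = [event(t.trial_id, 100.0 + 5 * j, rng.normal(0, 0.2),
                        rng.normal(0, 0.2))
                  for t in trials for j in range(3)]
        flipped_trials = [
            TrialRecord(**{**t.__dict__,
                           "cue_direction": ("left" if t.cue_direction == "right"
                                             else "right")})
            for t in trials]
        flipped_events = [
            OcularEvent.from_displacement(e.trial_id, e.kind, e.onset_ms,
                                          e.offset_ms, -e.dx_deg, e.dy_deg,
                                          e.peak_velocity_deg_s)
            for e in events]
        a = direction_density_map(self._aligned(events, trials))
        b = direction_density_map(self._aligned(flipped_events, flipped_trials))
        np.testing.assert_array_equal(a.density, b.density)

    def test_symmetric_directions_give_symmetric_map(self):
        rng = np.random.default_rng(3)
        trials = [trial(0, cue="right")]
        n = 5000
        dx = rng.normal(0, 0.2, n)
        events = [event("t000", 100.0 + 0.01 * i, float(d),
                        float(rng.normal(0, 0.2))) for i, d in enumerate(dx)]
        dmap = direction_density_map(self._aligned(events, trials))
        # horizontal marginal should be mirror-symmetric up to sampling noise
        marginal = dmap.density.sum(axis=1)
        asym = np.abs(marginal - marginal[::-1]).sum() / 2
        assert asym < 0.05
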
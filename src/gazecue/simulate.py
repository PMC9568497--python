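"""Synthetic gaze traces and behavioral trials with known ground truth.

The trace generator emulates fixational eye movements during a ~3-s trial:
slow drift (a scaled Gaussian random walk), Poisson-timed microsaccades with
lognormal amplitudes riding a raised-cosine velocity profile that obeys the
main-sequence relation, optional blinks (missing-pupil spans), and additive
sensor noise. Every injected event is returned as ground truth so detector
recovery can be scored exactly.

The behavioral generator produces a signal-detection observer: each subject
has a base sensitivity d', valid/invalid gaze cues shift the internal signal
by +/- half the configured cueing effect, and "present" is reported when the
signal exceeds a fixed criterion. The default design is the study layout:
30 subjects x 3 gazer conditions (intact, floating heads, headless bodies)
x 2 SOAs (200/500 ms) x 60 trials per condition-SOA cell, 50% target
presence, 50% cue validity among target-present trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .types import (ARRAY_DURATION_MS, CONDITIONS, CUE_DIRECTIONS, SOAS,
                    GazeTrace, OcularEvent, TrialRecord, TrialTimeline)

__all__ = [
    "TraceSimConfig", "BehaviorSimConfig", "TimelineJitter",
    "make_timeline", "simulate_trace", "simulate_behavior",
    "simulate_experiment", "DEFAULT_CUE_EFFECTS",
]

#: Default valid-minus-invalid d' shifts per condition x SOA, used as the
#: default cueing-effect structure for the behavioral generator.
DEFAULT_CUE_EFFECTS: dict[str, dict[int, float]] = {
    "intact": {200: 0.31, 500: 0.41},
    "floating_heads": {200: 0.29, 500: 0.05},
    "headless_bodies": {200: 0.22, 500: 0.07},
}


@dataclass(frozen=True)
class TimelineJitter:
    """Gaussian jitter (SD, ms) applied to each motion anchor around its mean."""

    sd_ms: float = 50.0


# Mean anchor times (ms) of the gazers' head and body motion.
_HEAD_ONSET_MEAN = 400.0
_HEAD_OFFSET_MEAN = 1800.0
_BODY_ONSET_MEAN = 600.0
_BODY_OFFSET_MEAN = 1700.0


def make_timeline(soa_ms: int, jitter: TimelineJitter | None = None,
                  rng: np.random.Generator | None = None) -> TrialTimeline:
    """Draw one trial's anchor times.

    Head motion spans ~400-1800 ms and body motion ~600-1700 ms on average;
    the gaze cue completes when the later motion ends, and the
    target/distractor array appears one SOA later for 800 ms. Draws that
    violate the ordering invariants are rejected and redrawn (at most 100
    times).
    """
    if int(soa_ms) not in SOAS:
        raise ConfigurationError(f"soa_ms must be one of {SOAS}, got {soa_ms!r}")
    jitter = jitter or TimelineJitter()
    rng = rng or np.random.default_rng()
    for _ in range(100):
        sd = jitter.sd_ms
        head_on = _HEAD_ONSET_MEAN + sd * rng.standard_normal()
        head_off = _HEAD_OFFSET_MEAN + sd * rng.standard_normal()
        body_on = _BODY_ONSET_MEAN + sd * rng.standard_normal()
        body_off = _BODY_OFFSET_MEAN + sd * rng.standard_normal()
        if not (0.0 <= head_on < head_off and 0.0 <= body_on < body_off):
            continue
        completion = max(head_off, body_off)
        return TrialTimeline(
            head_motion_onset_ms=head_on, head_motion_offset_ms=head_off,
            body_motion_onset_ms=body_on, body_motion_offset_ms=body_off,
            gaze_completion_ms=completion,
            array_onset_ms=completion + float(soa_ms),
            array_offset_ms=completion + float(soa_ms) + ARRAY_DURATION_MS,
        )
    raise ConfigurationError(
        "timeline jitter rejected 100 consecutive draws; reduce sd_ms")


@dataclass(frozen=True)
class TraceSimConfig:
    """Parameters of the fixational-trace generator.

    Notes
    -----
    With the raised-cosine velocity profile, amplitude ``A``, duration ``T``
    and peak velocity ``Vp`` satisfy ``A = Vp * T / 2``; the event duration is
    therefore derived from the main-sequence slope (``T = 2 / slope``) unless
    ``ms_duration_ms`` is set explicitly, in which case amplitude is still
    honored exactly and the effective slope becomes ``2000 / T``.
    """

    drift_sd_deg_per_sqrt_s: float = 0.025
    ms_rate_hz: float = 1.5
    amp_median_deg: float = 0.26
    amp_sigma_log: float = 0.55
    toward_cue_prob: float = 0.70
    main_seq_slope_per_s: float = 90.0
    ms_duration_ms: float | None = None
    direction_sd_rad: float = 0.35
    noise_sd_deg: float = 0.0015
    blink_prob_per_trial: float = 0.011
    blink_duration_ms: float = 150.0
    refractory_ms: float = 30.0
    sample_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ms_rate_hz", "amp_median_deg", "amp_sigma_log",
                     "main_seq_slope_per_s", "blink_duration_ms",
                     "sample_rate_hz"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ConfigurationError(f"TraceSimConfig.{name} must be >= 0")
        for name in ("toward_cue_prob", "blink_prob_per_trial"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"TraceSimConfig.{name} must be in [0, 1], got {p}")
        if self.ms_duration_ms is not None and self.ms_duration_ms <= 0:
            raise ConfigurationError("ms_duration_ms must be > 0 when set")

    @property
    def event_duration_ms(self) -> float:
        if self.ms_duration_ms is not None:
            return float(self.ms_duration_ms)
        return 2000.0 / self.main_seq_slope_per_s


def _raised_cosine_displacement(t_rel_ms: np.ndarray, duration_ms: float) -> np.ndarray:
    """Fraction of total displacement completed at each time within the event.

    Integral of the raised-cosine velocity profile
    v(t) = (Vp/2) * (1 - cos(2 pi t / T)); zero velocity at both endpoints.
    """
    u = np.clip(t_rel_ms / duration_ms, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _draw_onsets(rng: np.random.Generator, n_events: int, duration_ms: float,
                 event_ms: float, refractory_ms: float) -> np.ndarray:
    """Uniform event onsets with a hard-core separation.

    The count is preserved (so Poisson-count statistics hold); only onsets
    that would overlap another event or fall within its refractory gap are
    redrawn, up to 100 passes.
    """
    min_sep = event_ms + refractory_ms
    lo, hi = 0.0, duration_ms - event_ms
    if n_events * min_sep > duration_ms:
        raise ConfigurationError(
            f"cannot place {n_events} events of {event_ms:.1f} ms with "
            f"{refractory_ms:.1f} ms refractory gaps in {duration_ms:.0f} ms")
    onsets = np.sort(rng.uniform(lo, hi, size=n_events))
    for _ in range(100):
        if n_events < 2 or np.all(np.diff(onsets) >= min_sep):
            return onsets
        bad = np.zeros(n_events, dtype=bool)
        bad[1:] |= np.diff(onsets) < min_sep
        onsets[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
        onsets.sort()
    raise ConfigurationError(
        "could not place non-overlapping events after 100 redraws")


def simulate_trace(cfg: TraceSimConfig, timeline: TrialTimeline,
                   cue_direction: str, duration_ms: float | None = None,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "sim", trial_id: str = "t000",
                   ) -> tuple[GazeTrace, list[OcularEvent]]:
    """Simulate one trial's gaze trace plus its ground-truth event list.

    Microsaccade onsets follow a Poisson process at ``cfg.ms_rate_hz`` (with
    a refractory separation so injected events remain temporally distinct);
    amplitudes are lognormal around ``cfg.amp_median_deg``; the horizontal
    displacement sign matches the cue side with probability
    ``cfg.toward_cue_prob``. Injected events whose peak velocity and
    acceleration exceed the conventional saccade criteria (35 deg/s and
    9500 deg/s^2) are labeled ``saccade`` in the truth list, the remainder
    ``microsaccade``; a blink is a contiguous missing-pupil span.
    """
    if cue_direction not in CUE_DIRECTIONS:
        raise ConfigurationError(
            f"cue_direction must be one of {CUE_DIRECTIONS}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if duration_ms is None:
        duration_ms = timeline.array_offset_ms
    if duration_ms < timeline.array_offset_ms:
        raise ConfigurationError(
            "duration_ms must cover the trial through array offset")

    dt_ms = 1000.0 / cfg.sample_rate_hz
    n = int(round(duration_ms / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    x = np.zeros(n)
    y = np.zeros(n)
    pupil_valid = np.ones(n, dtype=bool)
    truth: list[OcularEvent] = []

    # fixational drift: Gaussian random walk scaled per sqrt(second)
    if cfg.drift_sd_deg_per_sqrt_s > 0:
        step_sd = cfg.drift_sd_deg_per_sqrt_s * math.sqrt(dt_ms / 1000.0)
        x += np.cumsum(rng.normal(0.0, step_sd, size=n))
        y += np.cumsum(rng.normal(0.0, step_sd, size=n))

    # microsaccades
    event_ms = cfg.event_duration_ms
    if cfg.ms_rate_hz > 0:
        n_events = rng.poisson(cfg.ms_rate_hz * duration_ms / 1000.0)
        onsets = _draw_onsets(rng, int(n_events), duration_ms, event_ms,
                              cfg.refractory_ms)
        toward_sign = 1.0 if cue_direction == "right" else -1.0
        for onset in onsets:
            amp = cfg.amp_median_deg * math.exp(
                cfg.amp_sigma_log * rng.standard_normal())
            phi = rng.normal(0.0, cfg.direction_sd_rad)
            sign = toward_sign if rng.random() < cfg.toward_cue_prob else -toward_sign
            dx = sign * amp * math.cos(phi)
            dy = amp * math.sin(phi)
            frac = _raised_cosine_displacement(t_ms - onset, event_ms)
            x += dx * frac
            y += dy * frac
            peak_v = 2.0 * amp / (event_ms / 1000.0)
            peak_a = math.pi * peak_v / (event_ms / 1000.0)
            kind = ("saccade" if peak_v > 35.0 and peak_a > 9500.0
                    else "microsaccade")
            truth.append(OcularEvent.from_displacement(
                trial_id, kind, onset, onset + event_ms, dx, dy, peak_v))

    # blink: one contiguous missing-pupil span
    if rng.random() < cfg.blink_prob_per_trial:
        b_on = rng.uniform(0.0, max(duration_ms - cfg.blink_duration_ms, 1.0))
        b_off = b_on + cfg.blink_duration_ms
        span = (t_ms >= b_on) & (t_ms <= b_off)
        pupil_valid[span] = False
        truth.append(OcularEvent(
            trial_id=trial_id, kind="blink", onset_ms=b_on, offset_ms=b_off,
            dx_deg=0.0, dy_deg=0.0, amplitude_deg=0.0, direction_rad=0.0,
            peak_velocity_deg_s=0.0))

    if cfg.noise_sd_deg > 0:
        x += rng.normal(0.0, cfg.noise_sd_deg, size=n)
        y += rng.normal(0.0, cfg.noise_sd_deg, size=n)

    truth.sort(key=lambda e: e.onset_ms)
    trace = GazeTrace(subject_id=subject_id, trial_id=trial_id, t_ms=t_ms,
                      x_deg=x, y_deg=y, pupil_valid=pupil_valid,
                      sample_rate_hz=cfg.sample_rate_hz)
    return trace, truth


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Parameters of the signal-detection behavioral generator.

    ``cue_effect_dprime[condition][soa]`` is the additive valid-minus-invalid
    sensitivity shift; the default structure uses the study-scale values.
    ``n_trials_per_condition`` is split evenly across the configured SOAs
    (120 trials/condition -> 60 per condition x SOA cell).
    """

    n_subjects: int = 30
    n_trials_per_condition: int = 120
    dprime_mean: float = 0.95
    dprime_sd: float = 0.40
    criterion: float = 0.77
    cue_effect_dprime: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_CUE_EFFECTS.items()})
    p_target: float = 0.5
    p_valid: float = 0.5
    conditions: tuple[str, ...] = CONDITIONS
    soas: tuple[int, ...] = SOAS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.dprime_sd < 0:
            raise ConfigurationError("dprime_sd must be >= 0")
        for name in ("p_target", "p_valid"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not self.cue_effect_dprime:
            raise ConfigurationError("cue_effect_dprime map must not be empty")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")
            for soa in self.soas:
                if cond not in self.cue_effect_dprime or \
                        int(soa) not in self.cue_effect_dprime[cond]:
                    raise ConfigurationError(
                        f"cue_effect_dprime missing entry for "
                        f"({cond!r}, {soa})")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero by redrawing."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))
    return np.clip(out, 0.0, None)


def simulate_behavior(cfg: BehaviorSimConfig,
                      rng: np.random.Generator | None = None,
                      jitter: TimelineJitter | None = None,
                      with_timelines: bool = True) -> list[TrialRecord]:
    """Generate one cohort's trial records.

    Each subject's base sensitivity ``d_s`` is Normal(dprime_mean, dprime_sd)
    truncated at zero. On target-present trials the internal signal is
    Normal(d_s + effect/2, 1) for valid cues and Normal(d_s - effect/2, 1)
    for invalid; target-absent signals are Normal(0, 1). The response is
    "present" iff the signal exceeds ``cfg.criterion``. Trial composition is
    exactly balanced within each subject x condition x SOA cell: ``p_target``
    of trials present and ``p_valid`` of those validly cued (cue directions
    left/right equiprobable).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_per_cell = cfg.n_trials_per_condition // len(cfg.soas)
    base_d = _truncated_normal(rng, cfg.dprime_mean, cfg.dprime_sd,
                               cfg.n_subjects)
    trials: list[TrialRecord] = []
    for s in range(cfg.n_subjects):
        subject_id = f"s{s + 1:02d}"
        for cond in cfg.conditions:
            for soa in cfg.soas:
                effect = float(cfg.cue_effect_dprime[cond][int(soa)])
                n_present = int(round(n_per_cell * cfg.p_target))
                n_valid = int(round(n_present * cfg.p_valid))
                present = np.zeros(n_per_cell, dtype=bool)
                present[:n_present] = True
                valid = np.zeros(n_per_cell, dtype=bool)
                valid[:n_valid] = True  # only meaningful where present
                order = rng.permutation(n_per_cell)
                present, valid = present[order], valid[order]

                shift = np.where(valid, effect / 2.0, -effect / 2.0)
                mean = np.where(present, base_d[s] + shift, 0.0)
                signal = rng.normal(mean, 1.0)
                resp_present = signal > cfg.criterion
                cue_dir = rng.choice(CUE_DIRECTIONS, size=n_per_cell)

                for i in range(n_per_cell):
                    timeline = (make_timeline(int(soa), jitter, rng)
                                if with_timelines else None)
                    validity = ("not_applicable" if not present[i]
                                else ("valid" if valid[i] else "invalid"))
                    trials.append(TrialRecord(
                        subject_id=subject_id,
                        trial_id=f"{subject_id}_{cond}_{soa}_{i:03d}",
                        condition=cond, soa_ms=int(soa),
                        target_present=bool(present[i]),
                        cue_validity=validity,
                        cue_direction=str(cue_dir[i]),
                        response="present" if resp_present[i] else "absent",
                        timeline=timeline,
                    ))
    return trials


def simulate_experiment(behavior_cfg: BehaviorSimConfig,
                        trace_cfg: TraceSimConfig,
                        rng: np.random.Generator | None = None,
                        toward_map: dict | None = None,
                        trace_subjects: int | None = None,
                        ) -> tuple[list[TrialRecord], list[GazeTrace],
                                   list[OcularEvent]]:
    """Full synthetic dataset: trials plus gaze traces with ground truth.

    ``toward_map`` optionally overrides the toward-cue probability per
    ``(condition, soa, validity)`` cell so direction biases can mirror the
    behavioral effect structure. ``trace_subjects`` limits trace generation
    to the first k subjects (traces dominate the compute cost; behavioral
    analyses always use the full cohort).
    """
    rng = rng if rng is not None else np.random.default_rng(behavior_cfg.seed)
    trials = simulate_behavior(behavior_cfg, rng=rng, with_timelines=True)
    keep = ({f"s{k + 1:02d}" for k in range(trace_subjects)}
            if trace_subjects is not None else None)
    traces: list[GazeTrace] = []
    truth: list[OcularEvent] = []
    for trial in trials:
        if keep is not None and trial.subject_id not in keep:
            continue
        cfg = trace_cfg
        if toward_map is not None:
            key = (trial.condition, trial.soa_ms, trial.cue_validity)
            if key in toward_map:
                cfg = replace_toward(trace_cfg, toward_map[key])
        trace, events = simulate_trace(
            cfg, trial.timeline, trial.cue_direction, rng=rng,
            subject_id=trial.subject_id, trial_id=trial.trial_id)
        traces.append(trace)
        truth.extend(events)
    return trials, traces, truth


def replace_toward(cfg: TraceSimConfig, p: float) -> TraceSimConfig:
    """Copy of ``cfg`` with a different toward-cue probability."""
    from dataclasses import replace
    return replace(cfg, toward_cue_prob=float(p))


#: Per-annotator annotation error SD (px) emulating how informative each
#: gazer condition is about the locus of gaze: heads are most informative,
#: bodies alone far less so.
DEFAULT_ANNOTATION_ERROR_SD_PX = {
    "intact": 100.0,
    "floating_heads": 90.0,
    "headless_bodies": 220.0,
}


def simulate_annotations(geometry, n_videos: int = 20,
                         frames_per_video: int = 5, n_annotators: int = 3,
                         error_sd_px: dict[str, float] | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> "pd.DataFrame":
    """Synthetic gaze-annotation table with known ground truth.

    Each video gets one true gazed location (uniform over the central 60%
    of the screen, constant across its frames); every annotator's estimate
    is the truth plus isotropic Gaussian error whose SD depends on the
    condition. Points are clipped to the screen rectangle.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng()
    error_sd_px = error_sd_px or DEFAULT_ANNOTATION_ERROR_SD_PX
    rows = []
    for cond, sd in error_sd_px.items():
        for v in range(n_videos):
            video_id = f"{cond}_v{v:03d}"
            tx = rng.uniform(0.2 * geometry.width_px, 0.8 * geometry.width_px)
            ty = rng.uniform(0.2 * geometry.height_px, 0.8 * geometry.height_px)
            for f in range(frames_per_video):
                for a in range(n_annotators):
                    ax = np.clip(tx + rng.normal(0.0, sd), 0, geometry.width_px)
                    ay = np.clip(ty + rng.normal(0.0, sd), 0, geometry.height_px)
                    rows.append({
                        "video_id": video_id, "condition": cond,
                        "frame_index": f, "annotator_id": f"a{a + 1}",
                        "annotated_x_px": ax, "annotated_y_px": ay,
                        "truth_x_px": tx, "truth_y_px": ty,
                    })
    return pd.DataFrame(rows)
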
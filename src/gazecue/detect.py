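"""Velocity-threshold detection of saccades, microsaccades, and blinks.

Microsaccades are found with the classic velocity-threshold approach: eye
velocity is estimated with a moving-average derivative, a robust
(median-based) per-trial velocity scale sigma is computed per component, and
samples whose velocity exceeds lambda * sigma (elliptically combined across
components by default) for at least a minimum duration form an event.
Events separated by less than a merge gap are merged; events that also meet
the conventional saccade criteria (sustained speed > 35 deg/s with peak
acceleration > 9500 deg/s^2) are labeled saccades, and events overlapping
missing-pupil spans are blinks.

Velocity is undefined for samples whose derivative window touches a
missing-pupil span; such samples cannot seed events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (ConfigurationError, DegenerateTrialError, JoinError,
                     ValidationError)
from .types import GazeTrace, OcularEvent, TrialRecord

__all__ = [
    "DetectorParams", "compute_velocity", "estimate_threshold",
    "detect_microsaccades", "detect_saccades_and_blinks", "detect_events",
    "check_fixation", "apply_trial_exclusions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorParams:
    """Detector thresholds and windows.

    ``lambda_`` scales the robust velocity SD into the microsaccade
    threshold; ``criterion`` selects the two-component elliptical test
    ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1`` (default) or a scalar test on speed.
    ``max_microsaccade_amp_deg`` optionally reclassifies large
    threshold-crossing events as saccades; off by default.
    """

    lambda_: float = 6.0
    min_duration_ms: float = 12.0
    saccade_velocity_deg_s: float = 35.0
    saccade_accel_deg_s2: float = 9500.0
    velocity_window_samples: int = 5
    merge_gap_ms: float = 12.0
    fixation_radius_deg: float = 1.5
    criterion: str = "elliptical"
    max_microsaccade_amp_deg: float | None = None

    def __post_init__(self) -> None:
        for name in ("lambda_", "min_duration_ms", "saccade_velocity_deg_s",
                     "saccade_accel_deg_s2", "merge_gap_ms",
                     "fixation_radius_deg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"DetectorParams.{name} must be > 0")
        w = self.velocity_window_samples
        if w < 3 or w % 2 == 0:
            raise ConfigurationError(
                f"velocity_window_samples must be odd and >= 3, got {w}")
        if self.criterion not in ("elliptical", "scalar"):
            raise ConfigurationError(
                f"criterion must be 'elliptical' or 'scalar', "
                f"got {self.criterion!r}")


def _ma_derivative(x: np.ndarray, dt_s: float, k: int) -> np.ndarray:
    """Moving-average derivative with half-window ``k``.

    Interior: v[n] = sum_{j=1..k} (x[n+j] - x[n-j]) / (dt * k * (k+1)).
    Edges shrink the half-window down to a one-sided difference at the
    boundary samples.
    """
    n = x.size
    v = np.empty(n)
    num = np.zeros(n - 2 * k)
    for j in range(1, k + 1):
        num += x[k + j:n - k + j] - x[k - j:n - k - j]
    v[k:n - k] = num / (dt_s * k * (k + 1))
    for i in range(k):  # shrunken windows at both edges
        ke = i  # max symmetric half-window available at sample i
        if ke >= 1:
            num_e = sum(x[i + j] - x[i - j] for j in range(1, ke + 1))
            v[i] = num_e / (dt_s * ke * (ke + 1))
            num_e = sum(x[n - 1 - i + j] - x[n - 1 - i - j]
                        for j in range(1, ke + 1))
            v[n - 1 - i] = num_e / (dt_s * ke * (ke + 1))
        else:
            v[0] = (x[1] - x[0]) / dt_s
            v[n - 1] = (x[n - 1] - x[n - 2]) / dt_s
    return v


def compute_velocity(trace: GazeTrace, window: int | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample velocity components, speed, and acceleration.

    Returns ``(vx, vy, speed, accel)`` in deg/s and deg/s^2. Samples whose
    derivative window overlaps a missing-pupil sample are NaN.
    """
    window = 5 if window is None else int(window)
    if window < 3 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 3, got {window}")
    n = len(trace)
    if n < window:
        raise ValidationError(
            f"trace {trace.trial_id!r}: length {n} < window {window}")
    k = (window - 1) // 2
    dt_s = trace.dt_ms / 1000.0
    vx = _ma_derivative(trace.x_deg, dt_s, k)
    vy = _ma_derivative(trace.y_deg, dt_s, k)

    bad = ~trace.pupil_valid
    if bad.any():
        near_bad = np.convolve(bad.astype(float), np.ones(2 * k + 1),
                               mode="same") > 0
        vx = np.where(near_bad, np.nan, vx)
        vy = np.where(near_bad, np.nan, vy)

    speed = np.hypot(vx, vy)
    accel = np.empty(n)
    accel[1:-1] = (speed[2:] - speed[:-2]) / (2.0 * dt_s)
    accel[0] = (speed[1] - speed[0]) / dt_s
    accel[-1] = (speed[-1] - speed[-2]) / dt_s
    return vx, vy, speed, accel


def _robust_sigma(v: np.ndarray) -> float:
    """Median-based velocity scale: sqrt(median(v^2) - median(v)^2)."""
    med = np.median(v)
    var = np.median(v * v) - med * med
    return float(np.sqrt(var)) if var > 0 else 0.0


def estimate_threshold(vx: np.ndarray, vy: np.ndarray, lambda_: float = 6.0,
                       ) -> tuple[float, float]:
    """Per-component velocity thresholds eta = lambda * sigma.

    sigma is the median-based robust scale of the within-trial velocity
    distribution. Raises :class:`DegenerateTrialError` when a component's
    scale is zero (constant velocity) or fewer than 10 finite samples exist.
    """
    etas = []
    for v in (vx, vy):
        finite = np.asarray(v, dtype=float)
        finite = finite[np.isfinite(finite)]
        if finite.size < 10:
            raise DegenerateTrialError(
                "need >= 10 finite velocity samples to estimate a threshold")
        sigma = _robust_sigma(finite)
        if sigma <= 0:
            raise DegenerateTrialError(
                "degenerate (zero) robust velocity scale")
        etas.append(lambda_ * sigma)
    return etas[0], etas[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, stop_idx) inclusive."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list[tuple[int, int]], gap_samples: float,
                ) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _is_saccade(speed: np.ndarray, accel: np.ndarray, start: int, stop: int,
                params: DetectorParams, dt_ms: float) -> bool:
    """Sustained speed above the saccade criterion plus an acceleration peak."""
    seg_speed = speed[start:stop + 1]
    seg_accel = accel[start:stop + 1]
    fast = np.nan_to_num(seg_speed) > params.saccade_velocity_deg_s
    longest = max(((b - a) * dt_ms for a, b in _runs(fast)), default=-1.0)
    if longest < params.min_duration_ms:
        return False
    peak_a = np.nanmax(np.abs(seg_accel)) if np.isfinite(seg_accel).any() else 0.0
    return bool(peak_a > params.saccade_accel_deg_s2)


def _summarize(trace: GazeTrace, speed: np.ndarray, start: int, stop: int,
               kind: str) -> OcularEvent:
    seg = speed[start:stop + 1]
    peak = float(np.nanmax(seg)) if np.isfinite(seg).any() else 0.0
    return OcularEvent.from_displacement(
        trace.trial_id, kind, trace.t_ms[start], trace.t_ms[stop],
        trace.x_deg[stop] - trace.x_deg[start],
        trace.y_deg[stop] - trace.y_deg[start], peak)


def _invalid_spans(trace: GazeTrace) -> list[tuple[int, int]]:
    return _runs(~trace.pupil_valid)


def _overlaps_span(start: int, stop: int, spans: list[tuple[int, int]]) -> bool:
    return any(a <= stop and b >= start for a, b in spans)


def detect_microsaccades(trace: GazeTrace, params: DetectorParams | None = None,
                         ) -> list[OcularEvent]:
    """Detect threshold-crossing events in one trace.

    Candidate samples exceed the lambda*sigma criterion; runs lasting at
    least ``min_duration_ms`` become events; events closer than
    ``merge_gap_ms`` merge. Events overlapping missing-pupil spans are
    reclassified as blinks, and events meeting the saccade velocity +
    acceleration criteria as saccades; the rest are microsaccades. A
    degenerate threshold yields an empty list with a logged warning.
    """
    params = params or DetectorParams()
    vx, vy, speed, accel = compute_velocity(trace,
                                            params.velocity_window_samples)
    try:
        if params.criterion == "elliptical":
            eta_x, eta_y = estimate_threshold(vx, vy, params.lambda_)
            with np.errstate(invalid="ignore"):
                crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
        else:
            finite = speed[np.isfinite(speed)]
            if finite.size < 10:
                raise DegenerateTrialError("too few finite speed samples")
            sigma = _robust_sigma(finite)
            if sigma <= 0:
                raise DegenerateTrialError("zero robust speed scale")
            with np.errstate(invalid="ignore"):
                crit = speed > params.lambda_ * sigma
    except DegenerateTrialError as exc:
        logger.warning("trial %s: %s; no events detected", trace.trial_id, exc)
        return []
    crit = np.nan_to_num(crit, nan=0.0).astype(bool)

    dt = trace.dt_ms
    runs = [(a, b) for a, b in _runs(crit) if (b - a) * dt >= params.min_duration_ms]
    runs = _merge_runs(runs, params.merge_gap_ms / dt)

    spans = _invalid_spans(trace)
    events = []
    for start, stop in runs:
        if _overlaps_span(start, stop, spans):
            kind = "blink"
        elif _is_saccade(speed, accel, start, stop, params, dt):
            kind = "saccade"
        else:
            kind = "microsaccade"
        ev = _summarize(trace, speed, start, stop, kind)
        if (kind == "microsaccade"
                and params.max_microsaccade_amp_deg is not None
                and ev.amplitude_deg > params.max_microsaccade_amp_deg):
            ev = _summarize(trace, speed, start, stop, "saccade")
        events.append(ev)
    return events


def detect_saccades_and_blinks(trace: GazeTrace,
                               params: DetectorParams | None = None,
                               ) -> list[OcularEvent]:
    """Detect saccades by the fixed velocity/acceleration criteria, plus
    blinks as missing-pupil spans.

    A saccade is a run of speed above ``saccade_velocity_deg_s`` lasting at
    least ``min_duration_ms`` whose peak |acceleration| exceeds
    ``saccade_accel_deg_s2``. Saccade runs overlapping (or within the merge
    gap of) a missing-pupil span are absorbed into a single blink event
    spanning the union, mirroring tracker semantics where a blink is a
    missing pupil during a saccadic transient.
    """
    params = params or DetectorParams()
    _, _, speed, accel = compute_velocity(trace, params.velocity_window_samples)
    dt = trace.dt_ms
    fast = np.nan_to_num(speed) > params.saccade_velocity_deg_s
    sac_runs = [
        (a, b) for a, b in _runs(fast)
        if (b - a) * dt >= params.min_duration_ms
        and _is_saccade(speed, accel, a, b, params, dt)
    ]
    blink_spans = _invalid_spans(trace)

    events: list[OcularEvent] = []
    gap = params.merge_gap_ms / dt
    used = np.zeros(len(sac_runs), dtype=bool)
    for span_start, span_stop in blink_spans:
        lo, hi = span_start, span_stop
        for i, (a, b) in enumerate(sac_runs):
            if a <= hi + gap and b >= lo - gap:
                lo, hi = min(lo, a), max(hi, b)
                used[i] = True
        events.append(_summarize(trace, speed, lo, hi, "blink"))
    for i, (a, b) in enumerate(sac_runs):
        if not used[i]:
            events.append(_summarize(trace, speed, a, b, "saccade"))
    events.sort(key=lambda e: e.onset_ms)
    return events


def detect_events(trace: GazeTrace, params: DetectorParams | None = None,
                  ) -> list[OcularEvent]:
    """All events of one trace: threshold-crossing events plus blink spans.

    Threshold events already reclassified as blinks are merged with their
    missing-pupil span so no two returned events overlap.
    """
    params = params or DetectorParams()
    ms_events = detect_microsaccades(trace, params)
    spans = _invalid_spans(trace)
    if not spans:
        return ms_events
    _, _, speed, _ = compute_velocity(trace, params.velocity_window_samples)
    dt = trace.dt_ms
    events = [e for e in ms_events if e.kind != "blink"]
    blink_evs = [e for e in ms_events if e.kind == "blink"]
    for span_start, span_stop in spans:
        lo_ms = trace.t_ms[span_start]
        hi_ms = trace.t_ms[span_stop]
        for e in blink_evs:
            if e.onset_ms <= hi_ms + params.merge_gap_ms and \
                    e.offset_ms >= lo_ms - params.merge_gap_ms:
                lo_ms, hi_ms = min(lo_ms, e.onset_ms), max(hi_ms, e.offset_ms)
        lo = int(round(lo_ms / dt))
        hi = int(round(hi_ms / dt))
        events.append(_summarize(trace, speed, lo, hi, "blink"))
    events.sort(key=lambda e: e.onset_ms)
    return events


def check_fixation(trace: GazeTrace, radius_deg: float = 1.5) -> bool:
    """True iff every valid-pupil sample stays within ``radius_deg`` of
    center (a break requires moving strictly beyond the radius)."""
    r = np.hypot(trace.x_deg[trace.pupil_valid],
                 trace.y_deg[trace.pupil_valid])
    return bool(r.size == 0 or np.max(r) <= radius_deg)


def apply_trial_exclusions(trials: list[TrialRecord],
                           events: list[OcularEvent],
                           traces: list[GazeTrace] | None = None,
                           fixation_radius_deg: float = 1.5,
                           ) -> tuple[list[TrialRecord], dict]:
    """Apply the study's exclusion rules and report the tallies.

    A trial is excluded when a blink event overlaps the video presentation
    ``[video_onset, array_offset]`` (reason ``blink_in_video``) or, failing
    that, when its trace leaves the fixation radius (``fixation_break``).
    Trials without a timeline cannot be screened for blinks and raise
    :class:`JoinError`, as do events whose trial id is unknown.
    """
    by_trial: dict[str, TrialRecord] = {t.trial_id: t for t in trials}
    events_by_trial: dict[str, list[OcularEvent]] = {}
    for e in events:
        if e.trial_id not in by_trial:
            raise JoinError(f"event references unknown trial {e.trial_id!r}")
        events_by_trial.setdefault(e.trial_id, []).append(e)
    traces_by_trial: dict[str, GazeTrace] = {}
    for tr in traces or []:
        if tr.trial_id not in by_trial:
            raise JoinError(f"trace references unknown trial {tr.trial_id!r}")
        traces_by_trial[tr.trial_id] = tr

    kept: list[TrialRecord] = []
    counts = {"blink_in_video": 0, "fixation_break": 0}
    for t in trials:
        reason = None
        t_events = events_by_trial.get(t.trial_id, [])
        if any(e.kind == "blink" for e in t_events):
            if t.timeline is None:
                raise JoinError(
                    f"trial {t.trial_id!r} has a blink but no timeline to "
                    f"locate the video window")
            end = t.timeline.array_offset_ms
            if any(e.kind == "blink" and e.onset_ms <= end and
                   e.offset_ms >= t.timeline.video_onset_ms
                   for e in t_events):
                reason = "blink_in_video"
        if reason is None and t.trial_id in traces_by_trial:
            if not check_fixation(traces_by_trial[t.trial_id],
                                  fixation_radius_deg):
                reason = "fixation_break"
        if reason is None:
            kept.append(t)
        else:
            counts[reason] += 1
    n = len(trials)
    report = {
        "n_trials": n,
        "n_excluded": n - len(kept),
        "counts": counts,
        "fractions": {k: (v / n if n else 0.0) for k, v in counts.items()},
    }
    return kept, report
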
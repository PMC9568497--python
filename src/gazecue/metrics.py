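"""Rate curves, cue-direction bias, amplitude summaries, and density maps.

All metrics operate on an *aligned* event table: detected events joined with
their trial's design cell and re-timed relative to a chosen anchor
(video onset, head-motion onset, or array onset). "Toward the cue" is
defined on the horizontal displacement sign only: a rightward cue makes
dx > 0 toward, a leftward cue makes dx < 0 toward; dx == 0 counts as
neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import events_to_frame
from .types import OcularEvent, TrialRecord

__all__ = [
    "ANCHORS", "RateCurve", "WindowBiasStat", "DensityMap",
    "align_events", "rate_curve", "trial_bias_table",
    "toward_cue_window_stats", "amplitude_summary", "direction_density_map",
]

ANCHORS = ("video_onset", "head_motion_onset", "array_onset")


def align_events(events: list[OcularEvent] | pd.DataFrame,
                 trials: list[TrialRecord], anchor: str = "video_onset",
                 ) -> pd.DataFrame:
    """Join events with trial metadata and re-time onsets to an anchor.

    Returns the event table with ``subject_id``, ``condition``, ``soa_ms``,
    ``cue_validity``, ``cue_direction`` and ``onset_rel_ms`` columns added.
    Raises :class:`ValidationError` naming the trial if the requested anchor
    is undefined (missing timeline).
    """
    if anchor not in ANCHORS:
        raise ValidationError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df = df.copy()
    anchors: dict[str, float] = {}
    meta: dict[str, tuple] = {}
    for t in trials:
        if t.timeline is None:
            raise ValidationError(
                f"trial {t.trial_id!r} has no timeline; anchor {anchor!r} "
                f"undefined")
        anchors[t.trial_id] = t.timeline.anchor(anchor)
        meta[t.trial_id] = (t.subject_id, t.condition, t.soa_ms,
                            t.cue_validity, t.cue_direction)
    unknown = set(df["trial_id"]) - set(anchors)
    if unknown:
        raise ValidationError(
            f"events reference trials without records: {sorted(unknown)[:5]}")
    df["onset_rel_ms"] = df["onset_ms"] - df["trial_id"].map(anchors)
    cols = ["subject_id", "condition", "soa_ms", "cue_validity",
            "cue_direction"]
    for i, c in enumerate(cols):
        df[c] = df["trial_id"].map({k: v[i] for k, v in meta.items()})
    return df


@dataclass(frozen=True)
class RateCurve:
    """Across-subject microsaccade rate time course.

    ``rate_hz`` is the across-subject mean of per-subject rates (event
    onsets per bin / trials / bin width); ``ci_low``/``ci_high`` bound the
    95% interval across subjects. Bins whose smoothing window spills past
    the analysis span are NaN-masked.
    """

    anchor: str
    bin_centers_ms: np.ndarray
    rate_hz: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: int
    n_trials: int
    per_subject_rate_hz: np.ndarray = field(repr=False, default=None)


def rate_curve(aligned: pd.DataFrame, trials: list[TrialRecord],
               span_ms: tuple[float, float] = (0.0, 1000.0),
               bin_ms: float = 1.0, smooth_ms: float = 100.0,
               anchor: str = "video_onset", kind: str = "microsaccade",
               ) -> RateCurve:
    """Per-subject binned event rates, boxcar-smoothed and averaged.

    Each subject's rate is (onset count per bin) / (that subject's trial
    count x bin seconds), smoothed with a centered boxcar of ``smooth_ms``.
    The group curve is the across-subject mean with a normal-theory 95%
    interval. Subjects are taken from ``trials`` (non-excluded), so zero
    event counts still contribute zero rates.
    """
    lo, hi = span_ms
    if hi <= lo:
        raise ValidationError("span_ms must satisfy end > start")
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    centers = (edges[:-1] + edges[1:]) / 2.0
    live = [t for t in trials if not t.excluded]
    subjects = sorted({t.subject_id for t in live})
    if not subjects:
        raise ValidationError("no non-excluded trials to form a rate curve")
    n_trials_per_subj = {
        s: sum(1 for t in live if t.subject_id == s) for s in subjects}

    sel = aligned[aligned["kind"] == kind] if kind is not None else aligned
    curves = np.zeros((len(subjects), centers.size))
    for i, s in enumerate(subjects):
        onsets = sel.loc[sel["subject_id"] == s, "onset_rel_ms"].to_numpy()
        counts, _ = np.histogram(onsets, bins=edges)
        curves[i] = counts / (n_trials_per_subj[s] * bin_ms / 1000.0)
    w = max(int(round(smooth_ms / bin_ms)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        curves = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, curves)
        half = w // 2  # acausal edge bins are masked, not extrapolated
        curves[:, :half] = np.nan
        if half > 0:
            curves[:, -half:] = np.nan
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
        mean = np.nanmean(curves, axis=0)
        if len(subjects) > 1:
            se = np.nanstd(curves, axis=0, ddof=1) / math.sqrt(len(subjects))
        else:
            se = np.full_like(mean, np.nan)
    return RateCurve(
        anchor=anchor, bin_centers_ms=centers, rate_hz=mean,
        ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se,
        n_subjects=len(subjects), n_trials=len(live),
        per_subject_rate_hz=curves)


def trial_bias_table(aligned: pd.DataFrame, trials: list[TrialRecord],
                     window_ms: tuple[float, float] = (400.0, 800.0),
                     kind: str = "microsaccade") -> pd.DataFrame:
    """Per-trial toward-cue counts within one time window.

    Events with onset in ``[start, end)`` are scored: toward when the
    horizontal displacement sign matches the cue side, away when it opposes
    it, zero when dx == 0. The per-trial proportion is
    n_toward / (n_toward + n_away) (NaN when the trial has only zero-dx
    events or none); per-trial signed degrees is the sum of +/-dx with +
    toward the cue. Trials with no events in the window appear with zero
    counts so callers can report how many contributed.
    """
    lo, hi = window_ms
    if hi <= lo:
        raise ValidationError("window_ms must satisfy end > start")
    sel = aligned[(aligned["kind"] == kind)
                  & (aligned["onset_rel_ms"] >= lo)
                  & (aligned["onset_rel_ms"] < hi)]
    side = sel["cue_direction"].map({"right": 1.0, "left": -1.0})
    signed = sel["dx_deg"] * side
    per_event = pd.DataFrame({
        "trial_id": sel["trial_id"],
        "toward": (signed > 0).astype(int),
        "away": (signed < 0).astype(int),
        "zero": (signed == 0).astype(int),
        "signed_dx": signed,
    })
    agg = per_event.groupby("trial_id").agg(
        n_toward=("toward", "sum"), n_away=("away", "sum"),
        n_zero=("zero", "sum"), signed_deg=("signed_dx", "sum"))
    rows = []
    for t in trials:
        if t.excluded:
            continue
        if t.trial_id in agg.index:
            r = agg.loc[t.trial_id]
            n_toward, n_away, n_zero = int(r.n_toward), int(r.n_away), int(r.n_zero)
            signed_deg = float(r.signed_deg)
        else:
            n_toward = n_away = n_zero = 0
            signed_deg = 0.0
        n_events = n_toward + n_away + n_zero
        n_signed = n_toward + n_away
        rows.append({
            "subject_id": t.subject_id, "trial_id": t.trial_id,
            "condition": t.condition, "soa_ms": t.soa_ms,
            "cue_validity": t.cue_validity, "cue_direction": t.cue_direction,
            "n_events": n_events, "n_toward": n_toward, "n_away": n_away,
            "n_zero": n_zero,
            "proportion_toward": (n_toward / n_signed if n_signed else math.nan),
            "signed_deg_toward": signed_deg if n_events else math.nan,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WindowBiasStat:
    """Aggregate toward-cue bias in one window position."""

    window_start_ms: float
    window_end_ms: float
    n_trials: int
    n_trials_with_events: int
    n_events: int
    n_toward: int
    n_away: int
    n_zero: int
    mean_proportion_toward: float
    mean_signed_deg_toward: float
    empty: bool


def _window_stat(table: pd.DataFrame, lo: float, hi: float) -> WindowBiasStat:
    with_events = table[table["n_events"] > 0]
    prop = table["proportion_toward"].dropna()
    signed = table["signed_deg_toward"].dropna()
    return WindowBiasStat(
        window_start_ms=lo, window_end_ms=hi, n_trials=len(table),
        n_trials_with_events=len(with_events),
        n_events=int(table["n_events"].sum()),
        n_toward=int(table["n_toward"].sum()),
        n_away=int(table["n_away"].sum()),
        n_zero=int(table["n_zero"].sum()),
        mean_proportion_toward=float(prop.mean()) if len(prop) else math.nan,
        mean_signed_deg_toward=float(signed.mean()) if len(signed) else math.nan,
        empty=len(with_events) == 0,
    )


def toward_cue_window_stats(aligned: pd.DataFrame, trials: list[TrialRecord],
                            window_width_ms: float = 400.0,
                            span_ms: tuple[float, float] | None = None,
                            step_ms: float = 200.0,
                            kind: str = "microsaccade",
                            ) -> list[WindowBiasStat]:
    """Toward-cue bias in sliding windows.

    With ``span_ms=None`` a single window ``[0, window_width_ms)`` relative
    to the chosen anchor is scored; otherwise windows of
    ``window_width_ms`` slide by ``step_ms`` across the span (the last
    window ends at the span end). Windows containing no events are returned
    flagged ``empty`` rather than dropped.
    """
    if span_ms is None:
        starts = [0.0]
    else:
        lo, hi = span_ms
        if hi - lo < window_width_ms:
            raise ValidationError("span shorter than the window width")
        starts = list(np.arange(lo, hi - window_width_ms + step_ms / 2,
                                step_ms))
    out = []
    for start in starts:
        table = trial_bias_table(aligned, trials,
                                 (start, start + window_width_ms), kind)
        out.append(_window_stat(table, start, start + window_width_ms))
    return out


def amplitude_summary(events: list[OcularEvent] | pd.DataFrame,
                      threshold_deg: float = 0.5,
                      hist_range_deg: tuple[float, float] = (0.0, 2.0),
                      hist_bins: int = 40) -> dict:
    """Median amplitude (arcmin), fraction strictly below a cutoff, and a
    fixed-bin histogram. An empty input yields a flagged empty summary."""
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    amps = df.loc[df["kind"] == "microsaccade", "amplitude_deg"] \
        .to_numpy(dtype=float) if len(df) else np.array([])
    if amps.size == 0:
        return {"n_events": 0, "median_arcmin": math.nan,
                "fraction_below_threshold": math.nan,
                "hist_counts": np.zeros(hist_bins, dtype=int),
                "hist_edges_deg": np.linspace(*hist_range_deg, hist_bins + 1),
                "empty": True}
    counts, edges = np.histogram(amps, bins=hist_bins, range=hist_range_deg)
    return {
        "n_events": int(amps.size),
        "median_arcmin": float(np.median(amps) * 60.0),
        "fraction_below_threshold": float(np.mean(amps < threshold_deg)),
        "hist_counts": counts, "hist_edges_deg": edges,
        "empty": False,
    }


@dataclass(frozen=True)
class DensityMap:
    """Cue-mirrored 2D displacement density (sums to 1; +x is toward)."""

    x_edges_deg: np.ndarray
    y_edges_deg: np.ndarray
    density: np.ndarray
    n_events: int
    empty: bool


def direction_density_map(aligned: pd.DataFrame,
                          grid_extent_deg: float = 1.0,
                          grid_bins: int = 41,
                          kind: str = "microsaccade") -> DensityMap:
    """2D histogram of event displacements with the cue side mirrored to +x.

    Left-cue trials are mirrored in x so "toward the cue" is always the +x
    half-plane; the map is normalized to sum to 1 (zero and flagged empty
    when no events fall on the grid).
    """
    sel = aligned[aligned["kind"] == kind]
    side = sel["cue_direction"].map({"right": 1.0, "left": -1.0}).to_numpy()
    dx = sel["dx_deg"].to_numpy(dtype=float) * side
    dy = sel["dy_deg"].to_numpy(dtype=float)
    edges = np.linspace(-grid_extent_deg, grid_extent_deg, grid_bins + 1)
    h, xe, ye = np.histogram2d(dx, dy, bins=[edges, edges])
    total = h.sum()
    return DensityMap(
        x_edges_deg=xe, y_edges_deg=ye,
        density=h / total if total > 0 else h,
        n_events=int(total), empty=total == 0)
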
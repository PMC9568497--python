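"""Readers and writers for the tabular artifacts of the pipeline.

All tables are delimited text (CSV by default, TSV accepted via the
``sep`` argument) with a header row. Floats are written with 17 significant
digits so a write -> read round trip reproduces values bit-identically.

Schemas
-------
samples:      trial, subject, time, x, y, pupil_valid   (one row per sample)
trials:       subject_id, trial_id, condition, soa_ms, target_present,
              cue_validity, cue_direction, response, excluded,
              exclusion_reason [+ timeline anchor columns]
events:       trial_id, kind, onset_ms, offset_ms, dx_deg, dy_deg,
              amplitude_deg, direction_rad, peak_velocity_deg_s
annotations:  video_id, condition, frame_index, annotator_id,
              annotated_x_px, annotated_y_px, truth_x_px, truth_y_px
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, SamplingError, ValidationError
from .geometry import ScreenGeometry
from .types import (GazeTrace, OcularEvent, TrialRecord, TrialTimeline,
                    CONDITIONS)

__all__ = [
    "read_gaze_samples", "write_gaze_samples",
    "read_trial_table", "write_trial_table",
    "read_event_table", "write_event_table",
    "read_annotations",
    "events_to_frame", "trials_to_frame",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

SAMPLE_COLUMNS = ("trial", "time", "x", "y", "pupil_valid")
EVENT_COLUMNS = ("trial_id", "kind", "onset_ms", "offset_ms", "dx_deg",
                 "dy_deg", "amplitude_deg", "direction_rad",
                 "peak_velocity_deg_s")
TRIAL_COLUMNS = ("subject_id", "trial_id", "condition", "soa_ms",
                 "target_present", "cue_validity", "cue_direction", "response",
                 "excluded", "exclusion_reason")
TIMELINE_COLUMNS = ("head_motion_onset_ms", "head_motion_offset_ms",
                    "body_motion_onset_ms", "body_motion_offset_ms",
                    "gaze_completion_ms", "array_onset_ms", "array_offset_ms")
ANNOTATION_COLUMNS = ("video_id", "condition", "frame_index", "annotator_id",
                      "annotated_x_px", "annotated_y_px", "truth_x_px",
                      "truth_y_px")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_gaze_samples(path, geometry: ScreenGeometry, units: str = "deg",
                      sample_rate_hz: float = 1000.0, sep: str = ",",
                      subject_id: str | None = None) -> list[GazeTrace]:
    """Read a per-sample gaze table and split it into one trace per trial.

    Parameters
    ----------
    path : path-like
    geometry : ScreenGeometry
        Used to convert pixel inputs to centered degrees.
    units : {"deg", "px"}
        Units of the x/y columns. Pixel coordinates use the image convention
        (origin top-left, +y down) and are converted to centered degrees.
    sample_rate_hz : float
        Expected sampling rate; timestamps are validated against it.
    subject_id : str, optional
        Subject id to stamp on all traces if the file has no ``subject``
        column.
    """
    if units not in ("deg", "px"):
        raise ValidationError(f"units must be 'deg' or 'px', got {units!r}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, path)
    traces: list[GazeTrace] = []
    for trial_id, group in df.groupby("trial", sort=True):
        group = group.sort_values("time")
        x = group["x"].to_numpy(dtype=float)
        y = group["y"].to_numpy(dtype=float)
        if units == "px":
            x, y = geometry.px_to_deg(x, y)
        if "subject" in group.columns:
            subj = str(group["subject"].iloc[0])
        else:
            subj = subject_id if subject_id is not None else "unknown"
        try:
            traces.append(GazeTrace(
                subject_id=subj, trial_id=str(trial_id),
                t_ms=group["time"].to_numpy(dtype=float),
                x_deg=x, y_deg=y,
                pupil_valid=group["pupil_valid"].to_numpy().astype(bool),
                sample_rate_hz=sample_rate_hz,
            ))
        except SamplingError as exc:
            raise SamplingError(f"{path}: {exc}") from exc
    return traces


def write_gaze_samples(traces: Sequence[GazeTrace], path, sep: str = ",") -> None:
    """Write traces as a per-sample table in degree units."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trial": tr.trial_id, "subject": tr.subject_id,
            "time": tr.t_ms, "x": tr.x_deg, "y": tr.y_deg,
            "pupil_valid": tr.pupil_valid.astype(int),
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["trial", "subject", *SAMPLE_COLUMNS[1:]])
    out.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def _timeline_from_row(row) -> TrialTimeline | None:
    if any(c not in row or pd.isna(row[c]) for c in TIMELINE_COLUMNS):
        return None
    return TrialTimeline(**{c: float(row[c]) for c in TIMELINE_COLUMNS})


def read_trial_table(path, sep: str = ",") -> list[TrialRecord]:
    """Read a trial metadata table into validated :class:`TrialRecord` rows.

    Enum fields are validated on construction; rows with unknown condition,
    SOA, validity, or response values raise :class:`ValidationError` naming
    the offending value and the allowed set. An empty file yields an empty
    list with a logged warning.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty trial table", path)
        return []
    _require_columns(df, TRIAL_COLUMNS[:8], path)
    records = []
    for _, row in df.iterrows():
        if str(row["condition"]) not in CONDITIONS:
            raise ValidationError(
                f"{path}: unknown condition {row['condition']!r}; "
                f"allowed: {list(CONDITIONS)}")
        records.append(TrialRecord(
            subject_id=str(row["subject_id"]), trial_id=str(row["trial_id"]),
            condition=str(row["condition"]), soa_ms=int(row["soa_ms"]),
            target_present=bool(int(row["target_present"])),
            cue_validity=str(row["cue_validity"]),
            cue_direction=str(row["cue_direction"]),
            response=str(row["response"]),
            timeline=_timeline_from_row(row),
            excluded=bool(int(row["excluded"])) if "excluded" in row and not pd.isna(row["excluded"]) else False,
            exclusion_reason=str(row["exclusion_reason"]) if "exclusion_reason" in row and not pd.isna(row["exclusion_reason"]) else "none",
        ))
    return records


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records (including timeline anchors) to a DataFrame."""
    rows = []
    for t in trials:
        row = {
            "subject_id": t.subject_id, "trial_id": t.trial_id,
            "condition": t.condition, "soa_ms": t.soa_ms,
            "target_present": int(t.target_present),
            "cue_validity": t.cue_validity, "cue_direction": t.cue_direction,
            "response": t.response, "excluded": int(t.excluded),
            "exclusion_reason": t.exclusion_reason,
        }
        if t.timeline is not None:
            for c in TIMELINE_COLUMNS:
                row[c] = getattr(t.timeline, c)
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_table(trials: Sequence[TrialRecord], path, sep: str = ",") -> None:
    df = trials_to_frame(trials)
    if df.empty:
        df = pd.DataFrame(columns=list(TRIAL_COLUMNS) + list(TIMELINE_COLUMNS))
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def events_to_frame(events: Sequence[OcularEvent]) -> pd.DataFrame:
    """Event list -> DataFrame sorted by (trial_id, onset_ms)."""
    df = pd.DataFrame(
        [{c: getattr(e, c) for c in EVENT_COLUMNS} for e in events],
        columns=list(EVENT_COLUMNS))
    return df.sort_values(["trial_id", "onset_ms"], kind="mergesort",
                          ignore_index=True)


def write_event_table(events: Sequence[OcularEvent], path, sep: str = ",") -> None:
    """Write events as delimited text, rows deterministically ordered by
    (trial_id, onset_ms). An empty list yields a header-only file."""
    events_to_frame(events).to_csv(path, sep=sep, index=False,
                                   float_format=FLOAT_FMT)


def read_event_table(path, sep: str = ",") -> list[OcularEvent]:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    _require_columns(df, EVENT_COLUMNS, path)
    return [
        OcularEvent(
            trial_id=str(row.trial_id), kind=str(row.kind),
            onset_ms=float(row.onset_ms), offset_ms=float(row.offset_ms),
            dx_deg=float(row.dx_deg), dy_deg=float(row.dy_deg),
            amplitude_deg=float(row.amplitude_deg),
            direction_rad=float(row.direction_rad),
            peak_velocity_deg_s=float(row.peak_velocity_deg_s),
        )
        for row in df.itertuples(index=False)
    ]


def read_annotations(path, geometry: ScreenGeometry | None = None,
                     sep: str = ",") -> pd.DataFrame:
    """Read a gaze-annotation table (one row per annotator x frame).

    Coordinates are pixels in the image convention. If ``geometry`` is given,
    coordinates are checked to lie on the screen rectangle.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    _require_columns(df, ANNOTATION_COLUMNS, path)
    bad = ~df["condition"].astype(str).isin(CONDITIONS)
    if bad.any():
        raise ValidationError(
            f"{path}: unknown condition value(s) "
            f"{sorted(df.loc[bad, 'condition'].unique())}; "
            f"allowed: {list(CONDITIONS)}")
    if geometry is not None:
        for cx, cy in (("annotated_x_px", "annotated_y_px"),
                       ("truth_x_px", "truth_y_px")):
            x = df[cx].to_numpy(dtype=float)
            y = df[cy].to_numpy(dtype=float)
            if ((x < 0) | (x > geometry.width_px) | (y < 0)
                    | (y > geometry.height_px)).any():
                raise ValidationError(
                    f"{path}: {cx}/{cy} outside the screen rectangle")
    return df
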
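"""Core record types shared across the pipeline.

A :class:`GazeTrace` is one trial's uniformly sampled eye-position stream in
centered degree coordinates. An :class:`OcularEvent` is a detected (or
ground-truth injected) saccade, microsaccade, or blink. A :class:`TrialRecord`
carries one trial's design cell, timeline anchors, response, and exclusion
status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SamplingError, ValidationError

__all__ = [
    "CONDITIONS", "SOAS", "VALIDITIES", "CUE_DIRECTIONS", "EVENT_KINDS",
    "RESPONSES", "EXCLUSION_REASONS", "ARRAY_DURATION_MS",
    "GazeTrace", "OcularEvent", "TrialTimeline", "TrialRecord",
]

CONDITIONS = ("intact", "floating_heads", "headless_bodies")
SOAS = (200, 500)
VALIDITIES = ("valid", "invalid", "not_applicable")
CUE_DIRECTIONS = ("left", "right")
EVENT_KINDS = ("saccade", "microsaccade", "blink")
RESPONSES = ("present", "absent")
EXCLUSION_REASONS = ("none", "blink_in_video", "fixation_break")

#: Target/distractor array presentation duration (ms).
ARRAY_DURATION_MS = 800.0


@dataclass
class GazeTrace:
    """One trial's eye-position stream.

    ``x_deg``/``y_deg`` are relative to screen center (+x rightward,
    +y upward); ``pupil_valid`` flags samples with a tracked pupil.
    Timestamps must be uniform at ``sample_rate_hz``.
    """

    subject_id: str
    trial_id: str
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil_valid: np.ndarray
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.pupil_valid = np.asarray(self.pupil_valid, dtype=bool)
        n = self.t_ms.size
        if not (self.x_deg.size == self.y_deg.size == self.pupil_valid.size == n):
            raise ValidationError(
                f"trial {self.trial_id!r}: per-sample arrays have unequal lengths")
        if n < 5:
            raise ValidationError(
                f"trial {self.trial_id!r}: need at least 5 samples, got {n}")
        dt = 1000.0 / self.sample_rate_hz
        diffs = np.diff(self.t_ms)
        if not np.allclose(diffs, dt, rtol=0.0, atol=1e-6 * dt + 1e-9):
            raise SamplingError(
                f"trial {self.trial_id!r}: timestamps are not uniform at "
                f"{self.sample_rate_hz} Hz (expected step {dt} ms)")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def __len__(self) -> int:
        return int(self.t_ms.size)


@dataclass(frozen=True)
class OcularEvent:
    """A detected or injected ocular event.

    ``dx_deg``/``dy_deg`` are the net displacement from onset to offset;
    ``amplitude_deg`` is its Euclidean norm and ``direction_rad`` its
    ``atan2(dy, dx)`` angle.
    """

    trial_id: str
    kind: str
    onset_ms: float
    offset_ms: float
    dx_deg: float
    dy_deg: float
    amplitude_deg: float
    direction_rad: float
    peak_velocity_deg_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.offset_ms > self.onset_ms:
            raise ValidationError(
                f"event in trial {self.trial_id!r}: offset must exceed onset")
        norm = math.hypot(self.dx_deg, self.dy_deg)
        if not math.isclose(self.amplitude_deg, norm, rel_tol=1e-6, abs_tol=1e-9):
            raise ValidationError(
                f"event in trial {self.trial_id!r}: amplitude {self.amplitude_deg} "
                f"does not match displacement norm {norm}")

    @classmethod
    def from_displacement(cls, trial_id: str, kind: str, onset_ms: float,
                          offset_ms: float, dx_deg: float, dy_deg: float,
                          peak_velocity_deg_s: float) -> "OcularEvent":
        return cls(
            trial_id=trial_id, kind=kind, onset_ms=float(onset_ms),
            offset_ms=float(offset_ms), dx_deg=float(dx_deg), dy_deg=float(dy_deg),
            amplitude_deg=math.hypot(dx_deg, dy_deg),
            direction_rad=math.atan2(dy_deg, dx_deg),
            peak_velocity_deg_s=float(peak_velocity_deg_s),
        )


@dataclass(frozen=True)
class TrialTimeline:
    """Trial anchor times in ms relative to video onset (which is 0).

    ``gaze_completion_ms`` is when the dynamic gaze cue finishes; the
    target/distractor array appears one SOA later and stays on for 800 ms.
    """

    head_motion_onset_ms: float
    head_motion_offset_ms: float
    body_motion_onset_ms: float
    body_motion_offset_ms: float
    gaze_completion_ms: float
    array_onset_ms: float
    array_offset_ms: float
    video_onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.head_motion_onset_ms < self.head_motion_offset_ms):
            raise ValidationError("head motion onset/offset out of order")
        if not (0.0 <= self.body_motion_onset_ms < self.body_motion_offset_ms):
            raise ValidationError("body motion onset/offset out of order")
        if not self.array_onset_ms > self.gaze_completion_ms:
            raise ValidationError("array onset must follow gaze completion")
        if not math.isclose(self.array_offset_ms - self.array_onset_ms,
                            ARRAY_DURATION_MS, rel_tol=0, abs_tol=1e-6):
            raise ValidationError(
                f"array presentation must last {ARRAY_DURATION_MS} ms")

    @property
    def soa_ms(self) -> float:
        return self.array_onset_ms - self.gaze_completion_ms

    def anchor(self, name: str) -> float:
        """Return an anchor time by name (used for event alignment)."""
        try:
            return float(getattr(self, f"{name}_ms"))
        except AttributeError:
            raise ValidationError(f"unknown timeline anchor {name!r}") from None


@dataclass
class TrialRecord:
    """One trial's design cell, timeline, response, and exclusion status."""

    subject_id: str
    trial_id: str
    condition: str
    soa_ms: int
    target_present: bool
    cue_validity: str
    cue_direction: str
    response: str
    timeline: TrialTimeline | None = None
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"trial {self.trial_id!r}: condition {self.condition!r} not in "
                f"{CONDITIONS}")
        if int(self.soa_ms) not in SOAS:
            raise ValidationError(
                f"trial {self.trial_id!r}: soa_ms {self.soa_ms!r} not in {SOAS}")
        self.soa_ms = int(self.soa_ms)
        if self.cue_validity not in VALIDITIES:
            raise ValidationError(
                f"trial {self.trial_id!r}: cue_validity {self.cue_validity!r} "
                f"not in {VALIDITIES}")
        if self.cue_direction not in CUE_DIRECTIONS:
            raise ValidationError(
                f"trial {self.trial_id!r}: cue_direction {self.cue_direction!r} "
                f"not in {CUE_DIRECTIONS}")
        if self.response not in RESPONSES:
            raise ValidationError(
                f"trial {self.trial_id!r}: response {self.response!r} not in "
                f"{RESPONSES}")
        if not self.target_present and self.cue_validity != "not_applicable":
            raise ValidationError(
                f"trial {self.trial_id!r}: target-absent trials must have "
                f"cue_validity='not_applicable'")
        if self.target_present and self.cue_validity == "not_applicable":
            raise ValidationError(
                f"trial {self.trial_id!r}: target-present trials need a "
                f"valid/invalid cue_validity")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValidationError(
                f"trial {self.trial_id!r}: unknown exclusion_reason "
                f"{self.exclusion_reason!r}")
        if self.excluded and self.exclusion_reason == "none":
            raise ValidationError(
                f"trial {self.trial_id!r}: excluded trials need a reason")

    def with_exclusion(self, reason: str) -> "TrialRecord":
        return replace(self, excluded=True, exclusion_reason=reason)
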
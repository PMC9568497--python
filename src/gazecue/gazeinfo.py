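"""Gaze information carried by human annotations of gazed locations.

For every annotated video frame the estimation error is the Euclidean
distance between the ground-truth gazed person's head location and the mean
annotated location across annotators. A permutation control reassigns
ground-truth locations across videos and recomputes the error, quantifying
the error expected by chance; informative annotations yield an observed
error below the permutation baseline.

Also provides the head-size trigonometry used to translate the angular size
of a person's head into a real-world viewing distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InferenceError, ValidationError
from .geometry import ScreenGeometry

__all__ = ["GazeInfoResult", "estimation_error", "permutation_baseline",
           "gaze_information", "head_angle_to_distance",
           "AVERAGE_HEAD_LENGTH_M"]

logger = logging.getLogger(__name__)

#: Average adult head vertical length (chin to crown), meters.
AVERAGE_HEAD_LENGTH_M = 0.24


@dataclass(frozen=True)
class GazeInfoResult:
    """Observed and chance-level gaze-location estimation error."""

    condition: str
    mean_error_px: float
    mean_error_deg: float
    n_frames: int
    baseline_mean_px: float
    baseline_mean_deg: float
    baseline_ci_px: tuple[float, float]
    n_permutations: int
    seed: int | None


def _px_per_deg(geometry: ScreenGeometry) -> float:
    if not math.isclose(geometry.ppd_x, geometry.ppd_y, rel_tol=1e-6):
        logger.warning(
            "anisotropic pixel raster (%.3f vs %.3f px/deg); degree errors "
            "use the horizontal factor", geometry.ppd_x, geometry.ppd_y)
    return geometry.ppd_x


def _frame_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Mean annotated point and ground truth per (video, frame)."""
    if annotations.empty:
        raise ValidationError("annotation table is empty")
    return annotations.groupby(["video_id", "frame_index"], sort=True).agg(
        condition=("condition", "first"),
        ann_x=("annotated_x_px", "mean"), ann_y=("annotated_y_px", "mean"),
        truth_x=("truth_x_px", "first"), truth_y=("truth_y_px", "first"),
    ).reset_index()


def estimation_error(annotations: pd.DataFrame, geometry: ScreenGeometry,
                     ) -> pd.DataFrame:
    """Mean per-condition estimation error (annotators averaged first).

    Returns one row per condition with ``mean_error_px``, ``mean_error_deg``
    and ``n_frames``.
    """
    frames = _frame_table(annotations)
    err = np.hypot(frames["ann_x"] - frames["truth_x"],
                   frames["ann_y"] - frames["truth_y"])
    frames = frames.assign(error_px=err)
    ppd = _px_per_deg(geometry)
    out = frames.groupby("condition", sort=True).agg(
        mean_error_px=("error_px", "mean"), n_frames=("error_px", "size"),
    ).reset_index()
    out["mean_error_deg"] = out["mean_error_px"] / ppd
    return out


def _mean_error_with_truths(frames: pd.DataFrame,
                            truth_by_video: pd.DataFrame,
                            video_order: np.ndarray) -> float:
    """Mean error when each video's truth comes from ``video_order``."""
    mapping = dict(zip(truth_by_video.index,
                       truth_by_video.to_numpy()[video_order]))
    truths = np.array([mapping[v] for v in frames["video_id"]])
    return float(np.mean(np.hypot(frames["ann_x"] - truths[:, 0],
                                  frames["ann_y"] - truths[:, 1])))


def permutation_baseline(annotations: pd.DataFrame, n_perm: int = 1000,
                         rng: np.random.Generator | None = None,
                         exhaustive: bool | None = None) -> dict:
    """Chance-level estimation error from permuted frame/truth pairings.

    Each permutation reassigns the per-video ground-truth location across
    videos (the permutation unit is the trial/movie) and recomputes the
    mean error over all frames. With ``exhaustive=True`` (automatic for
    <= 6 videos when unset) all permutations are enumerated instead of
    sampled.
    """
    rng = rng or np.random.default_rng()
    frames = _frame_table(annotations)
    truth_by_video = frames.groupby("video_id", sort=True)[
        ["truth_x", "truth_y"]].first()
    n_videos = len(truth_by_video)
    if n_videos < 2:
        raise InferenceError(
            "permutation baseline needs >= 2 distinct videos/trials")
    if exhaustive is None:
        exhaustive = n_videos <= 6
    if exhaustive:
        orders = [np.array(p) for p in
                  itertools.permutations(range(n_videos))]
    else:
        orders = [rng.permutation(n_videos) for _ in range(n_perm)]
    errors = np.array([
        _mean_error_with_truths(frames, truth_by_video, order)
        for order in orders])
    lo, hi = np.percentile(errors, [2.5, 97.5])
    return {"mean": float(errors.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "distribution": errors,
            "n_permutations": len(orders), "exhaustive": exhaustive}


def gaze_information(annotations: pd.DataFrame, geometry: ScreenGeometry,
                     n_perm: int = 1000,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> list[GazeInfoResult]:
    """Observed vs. permutation-baseline error per condition."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    ppd = _px_per_deg(geometry)
    observed = estimation_error(annotations, geometry)
    results = []
    for row in observed.itertuples(index=False):
        sub = annotations[annotations["condition"] == row.condition]
        base = permutation_baseline(sub, n_perm=n_perm, rng=rng)
        results.append(GazeInfoResult(
            condition=row.condition,
            mean_error_px=float(row.mean_error_px),
            mean_error_deg=float(row.mean_error_deg),
            n_frames=int(row.n_frames),
            baseline_mean_px=base["mean"],
            baseline_mean_deg=base["mean"] / ppd,
            baseline_ci_px=(base["ci_low"], base["ci_high"]),
            n_permutations=base["n_permutations"], seed=seed))
    return results


def head_angle_to_distance(head_vertical_angle_deg: float,
                           head_length_m: float = AVERAGE_HEAD_LENGTH_M,
                           ) -> float:
    """Viewing distance (m) that makes a head subtend a given vertical angle.

    distance = L / (2 * tan(theta / 2)) for head length L; e.g. a 0.24-m
    head subtending ~0.46 degrees corresponds to roughly 30 m.
    """
    theta = float(head_vertical_angle_deg)
    if not 0.0 < theta < 180.0:
        raise ValidationError(
            f"head angle must lie in (0, 180) degrees, got {theta}")
    if head_length_m <= 0:
        raise ValidationError("head length must be > 0")
    return head_length_m / (2.0 * math.tan(math.radians(theta) / 2.0))
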
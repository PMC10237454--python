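"""End-to-end video analysis: frames -> silhouette -> track -> subtask speeds."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from tugspeed.calibration import MarkerSet, build_calibration
from tugspeed.errors import UnusableTrackError
from tugspeed.foreground import (
    DEFAULT_MEDIAN_KERNEL,
    DEFAULT_TAU,
    largest_component,
    median_denoise,
    silhouette_centroid,
    subtract_and_threshold,
    to_grayscale,
)
from tugspeed.kinematics import (
    CentroidTrack,
    SpeedSeries,
    default_window,
    instantaneous_speed,
    track_to_world,
)
from tugspeed.segmentation import (
    SegmentationParams,
    SubtaskSpeeds,
    SyncEvents,
    TUGSegments,
    mean_subtask_speeds,
    segment,
)

__all__ = ["AnalysisResult", "extract_pixel_track", "analyze_frames"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    track: CentroidTrack
    speeds: SpeedSeries
    segments: TUGSegments
    subtask_speeds: SubtaskSpeeds

    def subtask_frame(self) -> pd.DataFrame:
        """One row per subtask: label, frame interval, duration, mean speed."""
        rows = []
        for k, (label, a, b) in enumerate(self.segments):
            rows.append(
                {
                    "label": label,
                    "start_frame": a,
                    "end_frame": b,
                    "duration_s": (b - a) / self.track.fps,
                    "mean_speed_ms": self.subtask_speeds.speeds[k],
                    "n_samples": self.subtask_speeds.n_samples[k],
                }
            )
        return pd.DataFrame(rows)

    def trajectory_frame(self) -> pd.DataFrame:
        """Per-frame trajectory with windowed speeds (NaN where undefined)."""
        n = len(self.track)
        vx = np.full(n, np.nan)
        vy = np.full(n, np.nan)
        vx[: len(self.speeds)] = self.speeds.speed_x
        vy[: len(self.speeds)] = self.speeds.speed_y
        return pd.DataFrame(
            {
                "frame": np.arange(n) + self.track.frame_offset,
                "t_s": self.track.t_s,
                "x_m": self.track.x_m,
                "y_m": self.track.y_m,
                "vx_ms": vx,
                "vy_ms": vy,
                "valid": self.track.valid.astype(int),
            }
        )


def extract_pixel_track(
    frames: Iterable[np.ndarray],
    background: np.ndarray,
    tau: float = DEFAULT_TAU,
    kernel: int = DEFAULT_MEDIAN_KERNEL,
    keep_largest: bool = False,
):
    """Per-frame silhouette centroids from a frame stream."""
    bg_gray = to_grayscale(background)
    centroids = []
    for frame in frames:
        mask = median_denoise(subtract_and_threshold(to_grayscale(frame), bg_gray, tau), kernel)
        if keep_largest:
            mask = largest_component(mask)
        centroids.append(silhouette_centroid(mask))
    n_invalid = sum(not c.valid for c in centroids)
    if n_invalid:
        logger.info("%d/%d frames had an empty silhouette", n_invalid, len(centroids))
    return centroids


def analyze_frames(
    frames: Iterable[np.ndarray],
    background: np.ndarray,
    markers: MarkerSet,
    sync: SyncEvents,
    fps: float = 60.0,
    tau: float = DEFAULT_TAU,
    kernel: int = DEFAULT_MEDIAN_KERNEL,
    window: int | None = None,
    params: SegmentationParams = SegmentationParams(),
    keep_largest: bool = False,
) -> AnalysisResult:
    """Run the full video pipeline for one trial.

    ``sync`` is given in original video frame indices; it is re-based if
    leading invalid frames were dropped from the track.
    """
    model = build_calibration(markers)
    centroids = extract_pixel_track(frames, background, tau, kernel, keep_largest)
    track = track_to_world(centroids, model, fps)
    local_sync = SyncEvents(
        start_frame=sync.start_frame - track.frame_offset,
        stop_frame=sync.stop_frame - track.frame_offset,
    )
    if local_sync.start_frame < 0:
        raise UnusableTrackError("sync start precedes the first valid frame")
    w = default_window(fps) if window is None else window
    speeds = instantaneous_speed(track, w)
    segments = segment(track, speeds, local_sync, params)
    subtasks = mean_subtask_speeds(segments, speeds)
    return AnalysisResult(track=track, speeds=speeds, segments=segments, subtask_speeds=subtasks)
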
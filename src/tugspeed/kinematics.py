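"""World-coordinate centroid track and windowed instantaneous speeds."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tugspeed.calibration import CalibrationModel, pixel_to_world
from tugspeed.errors import UnusableTrackError
from tugspeed.foreground import PixelCentroid

__all__ = ["CentroidTrack", "SpeedSeries", "track_to_world", "instantaneous_speed", "default_window"]

DEFAULT_WINDOW_FRAMES = 4
DEFAULT_FPS = 60.0
# The 4-frame window at 60 Hz spans 1/15 s; other rates preserve that span.
SPEED_WINDOW_S = DEFAULT_WINDOW_FRAMES / DEFAULT_FPS


def default_window(fps: float) -> int:
    """Window length in frames preserving the 1/15 s speed-estimation span."""
    return max(1, round(fps * SPEED_WINDOW_S))


@dataclass
class CentroidTrack:
    """Per-frame world-space centroid positions.

    ``frame_offset`` records the index of the first retained frame in the
    original video (leading invalid frames are dropped before the track is
    built), so sync events given in video frames can be re-based.
    """

    x_m: np.ndarray
    y_m: np.ndarray
    fps: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, dtype=np.float64)
        self.y_m = np.asarray(self.y_m, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(self.x_m.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.x_m.shape == self.y_m.shape == self.valid.shape):
            raise ValueError("x_m, y_m and valid must share one shape")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.x_m.size

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps


@dataclass
class SpeedSeries:
    """Signed windowed speeds; ``speed_x[i]`` covers frames ``[i, i+w]``."""

    speed_x: np.ndarray
    speed_y: np.ndarray
    window: int
    fps: float

    def __len__(self) -> int:
        return self.speed_x.size


def track_to_world(
    pixel_track: Sequence[PixelCentroid], model: CalibrationModel, fps: float = DEFAULT_FPS
) -> CentroidTrack:
    """Map pixel centroids to world metres, filling gaps by interpolation.

    Invalid frames (empty silhouette) interior to the track are linearly
    interpolated in world space from the nearest valid neighbours; leading
    and trailing invalid frames are dropped.  Requires at least two valid
    frames.
    """
    valid = np.array([c.valid for c in pixel_track], dtype=bool)
    if valid.sum() < 2:
        raise UnusableTrackError(f"need >= 2 valid frames, got {int(valid.sum())}")
    first = int(np.argmax(valid))
    last = len(valid) - 1 - int(np.argmax(valid[::-1]))
    u = np.array([c.u_px for c in pixel_track[first : last + 1]], dtype=np.float64)
    v = np.array([c.v_px for c in pixel_track[first : last + 1]], dtype=np.float64)
    keep = valid[first : last + 1]

    x, y = pixel_to_world(u, v, model)
    idx = np.arange(keep.size)
    if not keep.all():
        x[~keep] = np.interp(idx[~keep], idx[keep], x[keep])
        y[~keep] = np.interp(idx[~keep], idx[keep], y[keep])
    return CentroidTrack(x_m=x, y_m=y, fps=fps, valid=keep, frame_offset=first)


def instantaneous_speed(track: CentroidTrack, w: int = DEFAULT_WINDOW_FRAMES) -> SpeedSeries:
    """Signed secant speeds over a w-frame window.

    ``speed_x[i] = (x[i+w] - x[i]) / (w / fps)`` and analogously for y.
    Positive x speed points toward the turn mark, positive y speed upward.
    """
    if w < 1:
        raise UnusableTrackError(f"window must be >= 1 frame, got {w}")
    n = len(track)
    if n <= w:
        raise UnusableTrackError(f"track of {n} frames is too short for window {w}")
    dt = w / track.fps
    return SpeedSeries(
        speed_x=(track.x_m[w:] - track.x_m[:-w]) / dt,
        speed_y=(track.y_m[w:] - track.y_m[:-w]) / dt,
        window=w,
        fps=track.fps,
    )
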
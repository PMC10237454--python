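"""Motion-capture reference path: filtering, pelvis COM, subtask speeds.

The gold-standard trajectory is the arithmetic mean of four pelvis
markers (right/left ASIS and PSIS), low-pass filtered at 6 Hz with a
zero-phase fourth-order Butterworth, then pushed through the same
windowed-speed and nine-subtask segmentation machinery as the video path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from tugspeed.errors import InvalidInputError, InvalidParameterError
from tugspeed.kinematics import CentroidTrack, default_window, instantaneous_speed
from tugspeed.segmentation import (
    SegmentationParams,
    SubtaskSpeeds,
    SyncEvents,
    mean_subtask_speeds,
    segment,
)

__all__ = [
    "MARKER_NAMES",
    "MarkerTrack3D",
    "ComTrack",
    "butterworth_lowpass",
    "com_mocap",
    "mocap_subtask_speeds",
    "read_marker_csv",
]

MARKER_NAMES = ("R_ASIS", "L_ASIS", "R_PSIS", "L_PSIS")
_AXES = ("x", "y", "z")

DEFAULT_FS = 120.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_CUTOFF_HZ = 6.0


@dataclass
class MarkerTrack3D:
    """Four pelvis-marker trajectories, shape (n_frames, 4, 3), metres."""

    coords: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise InvalidInputError(
                f"expected (n, 4, 3) marker array, got shape {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise InvalidInputError("marker coordinates contain non-finite values")
        if self.fs <= 0:
            raise InvalidInputError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class ComTrack:
    """Centre-of-mass trajectory, shape (n_frames, 3), metres."""

    xyz: np.ndarray
    fs: float = DEFAULT_FS

    def __len__(self) -> int:
        return self.xyz.shape[0]


def butterworth_lowpass(
    track: MarkerTrack3D,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> MarkerTrack3D:
    """Zero-phase low-pass each coordinate channel.

    Forward-backward filtering (``filtfilt``) keeps filtered events aligned
    in time with the raw signal at the cost of doubling the effective
    order.
    """
    if cutoff_hz <= 0 or cutoff_hz >= track.fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={track.fs / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=track.fs, output="sos")
    flat = track.coords.reshape(len(track), -1)
    filtered = signal.sosfiltfilt(sos, flat, axis=0)
    return MarkerTrack3D(coords=filtered.reshape(track.coords.shape), fs=track.fs)


def com_mocap(track: MarkerTrack3D) -> ComTrack:
    """Per-frame arithmetic mean of the four markers on each axis."""
    return ComTrack(xyz=track.coords.mean(axis=1), fs=track.fs)


def mocap_subtask_speeds(
    com: ComTrack,
    sync: SyncEvents,
    params: SegmentationParams = SegmentationParams(),
    forward_axis: int = 0,
    up_axis: int = 2,
    window: int | None = None,
) -> SubtaskSpeeds:
    """Nine subtask mean speeds from the COM trajectory.

    The COM is projected onto (forward, up), re-using the video path's
    windowed-speed and segmentation code.  ``window`` defaults to the
    number of frames spanning the same 1/15 s as the video's 4-frame
    window (8 frames at 120 Hz).
    """
    if forward_axis == up_axis:
        raise InvalidInputError("forward_axis and up_axis must differ")
    track = CentroidTrack(
        x_m=com.xyz[:, forward_axis] - com.xyz[sync.start_frame, forward_axis],
        y_m=com.xyz[:, up_axis],
        fps=com.fs,
    )
    w = default_window(com.fs) if window is None else window
    speeds = instantaneous_speed(track, w)
    segments = segment(track, speeds, sync, params)
    return mean_subtask_speeds(segments, speeds)


def read_marker_csv(path, fs: float = DEFAULT_FS, millimetres: bool = False) -> MarkerTrack3D:
    """Read a marker table with columns ``<MARKER>_<axis>`` in metres.

    Expected header: ``R_ASIS_x, R_ASIS_y, ..., L_PSIS_z`` (order free).
    ``millimetres=True`` divides by 1000 on read.
    """
    df = pd.read_csv(path)
    cols = [f"{m}_{a}" for m in MARKER_NAMES for a in _AXES]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"marker CSV missing columns: {missing}")
    arr = df[cols].to_numpy(dtype=np.float64).reshape(len(df), 4, 3)
    if millimetres:
        arr = arr / 1000.0
    return MarkerTrack3D(coords=arr, fs=fs)


def write_marker_csv(track: MarkerTrack3D, path) -> None:
    """Write the marker table in the dialect of :func:`read_marker_csv`."""
    cols = [f"{m}_{a}" for m in MARKER_NAMES for a in _AXES]
    df = pd.DataFrame(track.coords.reshape(len(track), -1), columns=cols)
    df.to_csv(path, index=False, float_format="%.6f")
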
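"""Split a TUG trial into its nine subtasks and average their speeds.

Subtasks (half-open frame intervals, contiguous, tiling [start, stop)):

    V1 sit-to-stand        vertical speed
    V2 walk out  0 -> 1 m  horizontal speed
    V3 walk out  1 -> 2 m
    V4 walk out  2 m -> turn onset
    V5 turn
    V6 walk back turn exit -> 2 m
    V7 walk back 2 -> 1 m
    V8 walk back 1 m -> sit onset
    V9 stand-to-sit        vertical speed

Boundary rules (the source material defines the subtasks but not how to
find their edges, so these are this module's own, parameterised rules):

* standing height = median height over the middle third of the outbound
  walk; V1 ends at the first frame within ``stand_epsilon_m`` of it, V9
  starts at the last frame still within it;
* metre crossings are sign changes of ``x - mark`` assigned to the later
  frame, searched forward before the turn and backward after it;
* the turn is the contiguous excursion within ``turn_margin_m`` of the
  peak forward position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tugspeed.errors import InvalidInputError, SegmentationError
from tugspeed.kinematics import CentroidTrack, SpeedSeries

__all__ = [
    "SyncEvents",
    "SegmentationParams",
    "TUGSegments",
    "SubtaskSpeeds",
    "SegmentationError",
    "SUBTASK_LABELS",
    "detect_stand_complete",
    "detect_sit_begin",
    "detect_meter_crossings",
    "detect_turn",
    "segment",
    "mean_subtask_speeds",
]

logger = logging.getLogger(__name__)

SUBTASK_LABELS = (
    "V1_sit_to_stand",
    "V2_walk_out_0_1",
    "V3_walk_out_1_2",
    "V4_walk_out_2_3",
    "V5_turn",
    "V6_walk_back_3_2",
    "V7_walk_back_2_1",
    "V8_walk_back_1_0",
    "V9_stand_to_sit",
)

#: Subtasks whose speed is vertical (indices into SUBTASK_LABELS).
_VERTICAL = frozenset({0, 8})

_MIN_INTERVAL = 2  # frames


@dataclass(frozen=True)
class SyncEvents:
    """Trial start/stop frames from the synchronization annotations.

    ``start_frame`` is the first frame of sit-to-stand (trigger released),
    ``stop_frame`` the first frame after stand-to-sit completes (trigger
    pressed); both are indices into the centroid track.
    """

    start_frame: int
    stop_frame: int

    def validate(self, n_frames: int) -> None:
        if not (0 <= self.start_frame < self.stop_frame <= n_frames):
            raise InvalidInputError(
                f"sync events ({self.start_frame}, {self.stop_frame}) do not fit "
                f"a {n_frames}-frame track"
            )


@dataclass(frozen=True)
class SegmentationParams:
    stand_epsilon_m: float = 0.05
    turn_margin_m: float = 0.20
    meter_marks_m: tuple[float, ...] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.stand_epsilon_m <= 0 or self.turn_margin_m <= 0:
            raise InvalidInputError("stand_epsilon_m and turn_margin_m must be positive")
        if self.turn_margin_m >= 1.0:
            raise InvalidInputError(f"turn_margin_m must be < 1 m, got {self.turn_margin_m}")
        if any(m <= 0 for m in self.meter_marks_m):
            raise InvalidInputError("meter marks must be positive")


@dataclass(frozen=True)
class TUGSegments:
    """Nine labelled half-open frame intervals covering [start, stop)."""

    starts: tuple[int, ...]
    ends: tuple[int, ...]
    labels: tuple[str, ...] = SUBTASK_LABELS

    def __post_init__(self) -> None:
        if len(self.starts) != 9 or len(self.ends) != 9:
            raise SegmentationError("expected exactly 9 intervals")
        for k in range(9):
            if self.ends[k] - self.starts[k] < _MIN_INTERVAL:
                raise SegmentationError(
                    f"{self.labels[k]} spans [{self.starts[k]}, {self.ends[k]}): "
                    f"fewer than {_MIN_INTERVAL} frames"
                )
            if k and self.starts[k] != self.ends[k - 1]:
                raise SegmentationError(
                    f"{self.labels[k - 1]} -> {self.labels[k]} boundary mismatch: "
                    f"{self.ends[k - 1]} vs {self.starts[k]}"
                )

    def __iter__(self):
        return iter(zip(self.labels, self.starts, self.ends))


@dataclass(frozen=True)
class SubtaskSpeeds:
    """Mean absolute speed per subtask, in m/s."""

    speeds: tuple[float, ...]
    n_samples: tuple[int, ...]
    labels: tuple[str, ...] = SUBTASK_LABELS

    def as_array(self) -> np.ndarray:
        return np.asarray(self.speeds, dtype=np.float64)

    def __getitem__(self, k: int) -> float:
        """1-based access: speeds[1] is V1."""
        if not 1 <= k <= 9:
            raise IndexError(f"subtask index must be 1..9, got {k}")
        return self.speeds[k - 1]


def _standing_height(track: CentroidTrack, sync: SyncEvents) -> float:
    """Median height over the middle third of the outbound walk.

    The outbound walk is approximated by [start, forward-peak frame]; its
    middle third excludes both the chair rise and the turn approach.
    """
    x = track.x_m[sync.start_frame : sync.stop_frame]
    peak = sync.start_frame + int(np.argmax(x))
    span = peak - sync.start_frame
    lo = sync.start_frame + span // 3
    hi = sync.start_frame + (2 * span) // 3
    if hi <= lo:
        raise SegmentationError("outbound walk too short to estimate standing height")
    return float(np.median(track.y_m[lo : hi + 1]))


def detect_stand_complete(
    track: CentroidTrack, sync: SyncEvents, params: SegmentationParams = SegmentationParams()
) -> int:
    """First frame at/after start whose height reaches the standing band."""
    sync.validate(len(track))
    thresh = _standing_height(track, sync) - params.stand_epsilon_m
    y = track.y_m[sync.start_frame : sync.stop_frame]
    above = np.nonzero(y >= thresh)[0]
    if above.size == 0:
        raise SegmentationError("height never reaches the standing band after start")
    frame = sync.start_frame + int(above[0])
    if frame <= sync.start_frame:
        frame = sync.start_frame + _MIN_INTERVAL
        logger.warning("track already at standing height at start; V1 clamped to %d frames",
                       _MIN_INTERVAL)
    return frame


def detect_sit_begin(
    track: CentroidTrack, sync: SyncEvents, params: SegmentationParams = SegmentationParams()
) -> int:
    """Last frame before stop whose height is still in the standing band."""
    sync.validate(len(track))
    thresh = _standing_height(track, sync) - params.stand_epsilon_m
    y = track.y_m[sync.start_frame : sync.stop_frame]
    above = np.nonzero(y >= thresh)[0]
    if above.size == 0:
        raise SegmentationError("height never reaches the standing band before stop")
    frame = sync.start_frame + int(above[-1])
    if frame >= sync.stop_frame - _MIN_INTERVAL:
        frame = sync.stop_frame - _MIN_INTERVAL
        logger.warning("track still at standing height at stop; V9 clamped to %d frames",
                       _MIN_INTERVAL)
    return frame


def detect_turn(
    track: CentroidTrack,
    params: SegmentationParams = SegmentationParams(),
    sync: SyncEvents | None = None,
) -> tuple[int, int]:
    """Contiguous excursion within ``turn_margin_m`` of the forward peak.

    Returns (first, last) frame of the excursion, inclusive.
    """
    lo, hi = (sync.start_frame, sync.stop_frame) if sync is not None else (0, len(track))
    x = track.x_m[lo:hi]
    peak_i = int(np.argmax(x))
    thresh = x[peak_i] - params.turn_margin_m
    above = x > thresh
    # contiguous region containing the peak
    start = peak_i
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak_i
    while end < above.size - 1 and above[end + 1]:
        end += 1
    if start == 0 or end == above.size - 1:
        raise SegmentationError(
            "turn excursion touches the trial boundary: no return walk detected"
        )
    return lo + start, lo + end


def detect_meter_crossings(
    track: CentroidTrack,
    marks: Sequence[float] = (1.0, 2.0),
    sync: SyncEvents | None = None,
    turn: tuple[int, int] | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[dict[float, int], dict[float, int]]:
    """Frames at which x crosses each walkway mark, out and back.

    A crossing is a sign change of ``x - mark`` between consecutive frames,
    assigned to the later frame.  Outbound crossings are searched before
    the turn, inbound crossings after it.

    Returns ``(outbound, inbound)`` dicts keyed by mark.
    """
    lo, hi = (sync.start_frame, sync.stop_frame) if sync is not None else (0, len(track))
    if turn is None:
        turn = detect_turn(track, params, sync)
    x = track.x_m
    if float(np.max(x[lo:hi])) < max(marks):
        raise SegmentationError(
            f"track never reaches the {max(marks)} m mark (max x = {np.max(x[lo:hi]):.3f} m)"
        )
    outbound: dict[float, int] = {}
    inbound: dict[float, int] = {}
    for m in marks:
        hit = np.nonzero((x[lo : turn[0]] < m) & (x[lo + 1 : turn[0] + 1] >= m))[0]
        if hit.size == 0:
            raise SegmentationError(f"no outbound crossing of the {m} m mark")
        outbound[m] = lo + int(hit[0]) + 1
        hit = np.nonzero((x[turn[1] : hi - 1] > m) & (x[turn[1] + 1 : hi] <= m))[0]
        if hit.size == 0:
            raise SegmentationError(f"no inbound crossing of the {m} m mark")
        inbound[m] = turn[1] + int(hit[0]) + 1
    return outbound, inbound


def segment(
    track: CentroidTrack,
    speeds: SpeedSeries | None,
    sync: SyncEvents,
    params: SegmentationParams = SegmentationParams(),
) -> TUGSegments:
    """Run all boundary detectors and assemble the nine intervals.

    ``speeds`` is accepted for interface symmetry with
    :func:`mean_subtask_speeds` but boundaries depend only on the track.
    """
    sync.validate(len(track))
    turn = detect_turn(track, params, sync)
    outbound, inbound = detect_meter_crossings(track, params.meter_marks_m, sync, turn, params)
    stand_complete = detect_stand_complete(track, sync, params)
    sit_begin = detect_sit_begin(track, sync, params)
    m_lo, m_hi = min(params.meter_marks_m), max(params.meter_marks_m)
    boundaries = [
        sync.start_frame,
        stand_complete,
        outbound[m_lo],
        outbound[m_hi],
        turn[0],
        turn[1] + 1,
        inbound[m_hi],
        inbound[m_lo],
        sit_begin,
        sync.stop_frame,
    ]
    for k in range(9):
        if boundaries[k + 1] - boundaries[k] < _MIN_INTERVAL:
            raise SegmentationError(
                f"boundaries out of order at {SUBTASK_LABELS[k]}: "
                f"[{boundaries[k]}, {boundaries[k + 1]})"
            )
    return TUGSegments(starts=tuple(boundaries[:9]), ends=tuple(boundaries[1:]))


def mean_subtask_speeds(segments: TUGSegments, speeds: SpeedSeries) -> SubtaskSpeeds:
    """Average the absolute windowed speed over each subtask interval.

    Sit-to-stand and stand-to-sit use vertical speed; the walking and
    turning subtasks use horizontal speed.  The speed sample at index i
    describes the window starting at frame i; samples beyond the series
    length (trailing w frames) are unavailable and excluded.
    """
    abs_x = np.abs(speeds.speed_x)
    abs_y = np.abs(speeds.speed_y)
    means: list[float] = []
    counts: list[int] = []
    for k, (label, a, b) in enumerate(segments):
        b_eff = min(b, len(speeds))
        if b_eff <= a:
            raise SegmentationError(f"{label} holds no speed samples ([{a}, {b}))")
        series = abs_y if k in _VERTICAL else abs_x
        means.append(float(series[a:b_eff].mean()))
        counts.append(b_eff - a)
    return SubtaskSpeeds(speeds=tuple(means), n_samples=tuple(counts))
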
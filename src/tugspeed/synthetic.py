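"""Synthetic TUG trials with exact ground truth.

A trial is scripted as a piecewise-smooth planar centre-of-mass path:
smoothstep rise from the chair, constant per-metre walking speeds out to
the turn, a cosine excursion to the 3 m peak and back, constant per-metre
speeds home, smoothstep descent.  From one :class:`GroundTruth` the
package can render a sagittal video (rectangle-plus-head silhouette whose
analytic centroid equals the scripted COM), sample four pelvis markers at
the mocap rate, and report rule-based true subtask boundaries and mean
speeds for validation.

A seated-posture forward offset of the centroid is included so the
silhouette centroid, like a real seated silhouette, sits ahead of the
standing-column centroid while on the chair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from tugspeed.agreement import PairedTable
from tugspeed.calibration import CalibrationModel, MarkerSet, build_calibration
from tugspeed.errors import InvalidConfigError, InvalidParameterError
from tugspeed.kinematics import CentroidTrack
from tugspeed.mocap import MarkerTrack3D
from tugspeed.segmentation import SegmentationParams, SyncEvents, segment

__all__ = [
    "TrialConfig",
    "GroundTruth",
    "simulate_trajectory",
    "render_background",
    "render_frames",
    "simulate_mocap",
    "simulate_paired",
    "random_trial_config",
]

_DENSE_HZ = 600.0

# per-purpose stream tags for the counter-based seed split
_STREAM_VIDEO_NOISE = 7
_STREAM_MOCAP_NOISE = 11
_STREAM_PAIRED = 13


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class TrialConfig:
    """Full parametrization of one synthetic trial.

    Walking speeds are scripted per outbound/inbound metre (three values
    each, V2-V4 and V6-V8 order); the turn is a cosine excursion of
    ``turn_depth_m`` lasting ``turn_s``.
    """

    # phase script
    sit_to_stand_s: float = 1.2
    walk_out_speeds_ms: tuple[float, float, float] = (1.00, 1.10, 1.00)
    turn_s: float = 1.5
    walk_back_speeds_ms: tuple[float, float, float] = (1.00, 1.05, 0.95)
    stand_to_sit_s: float = 1.4
    lead_s: float = 0.6
    tail_s: float = 0.6
    turn_depth_m: float = 0.30
    walkway_m: float = 3.0
    # body geometry
    height_m: float = 1.70
    width_m: float = 0.45
    seated_height_m: float = 1.25
    head_radius_m: float = 0.10
    head_gap_m: float = 0.02
    seated_offset_m: float = 0.08
    transfer_blend_m: float = 0.07
    com_height_ratio: float = 0.55
    # camera geometry (defaults: 640x360, 3 m = 500 px, 0.5 m = 80 px)
    image_w: int = 640
    image_h: int = 360
    m1_px: tuple[float, float] = (560.0, 330.0)
    m2_px: tuple[float, float] = (60.0, 330.0)
    m3_px: tuple[float, float] = (30.0, 330.0)
    m4_px: tuple[float, float] = (30.0, 250.0)
    dist_x_m: float = 3.0
    dist_y_m: float = 0.5
    background_level: int = 40
    body_level: int = 200
    marker_level: int = 255
    # rates and noise
    fps_video: float = 60.0
    fs_mocap: float = 120.0
    noise_salt_pepper: float = 0.0
    mocap_noise_sd_m: float = 0.0
    marker_lateral_m: float = 0.12
    marker_ap_m: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "sit_to_stand_s": self.sit_to_stand_s,
            "turn_s": self.turn_s,
            "stand_to_sit_s": self.stand_to_sit_s,
            "lead_s": self.lead_s,
            "tail_s": self.tail_s,
            "turn_depth_m": self.turn_depth_m,
            "walkway_m": self.walkway_m,
            "fps_video": self.fps_video,
            "fs_mocap": self.fs_mocap,
        }
        for name, v in positive.items():
            if v <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        if any(s <= 0 for s in self.walk_out_speeds_ms + self.walk_back_speeds_ms):
            raise InvalidConfigError("walking speeds must all be positive")
        if self.turn_depth_m >= 1.0:
            raise InvalidConfigError("turn_depth_m must be < 1 m")
        if self.seated_height_m >= self.height_m:
            raise InvalidConfigError("seated_height_m must be below height_m")
        if not 0.0 <= self.noise_salt_pepper < 0.5:
            raise InvalidConfigError("noise_salt_pepper must lie in [0, 0.5)")

    @property
    def stand_com_m(self) -> float:
        return self.com_height_ratio * self.height_m

    @property
    def seated_com_m(self) -> float:
        return self.com_height_ratio * self.seated_height_m

    def marker_set(self) -> MarkerSet:
        return MarkerSet(
            m1_px=self.m1_px,
            m2_px=self.m2_px,
            m3_px=self.m3_px,
            m4_px=self.m4_px,
            dist_x_m=self.dist_x_m,
            dist_y_m=self.dist_y_m,
        )

    def calibration(self) -> CalibrationModel:
        return build_calibration(self.marker_set())


@dataclass
class GroundTruth:
    """Scripted trajectory plus rule-based subtask boundaries and speeds."""

    config: TrialConfig
    t_dense: np.ndarray
    x_dense: np.ndarray
    y_dense: np.ndarray
    sync: SyncEvents
    boundary_frames: tuple[int, ...]  # 10 boundaries of the 9 intervals
    true_speeds: tuple[float, ...]  # 9 path-length / duration means, m/s
    n_frames: int

    def com_at(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated COM at arbitrary times (seconds)."""
        times = np.asarray(times, dtype=np.float64)
        return (
            np.interp(times, self.t_dense, self.x_dense),
            np.interp(times, self.t_dense, self.y_dense),
        )

    def frame_com(self) -> tuple[np.ndarray, np.ndarray]:
        """COM at the video frame times."""
        return self.com_at(np.arange(self.n_frames) / self.config.fps_video)

    def sync_at(self, fs: float) -> SyncEvents:
        """Sync events re-expressed at another sampling rate."""
        scale = fs / self.config.fps_video
        return SyncEvents(
            start_frame=round(self.sync.start_frame * scale),
            stop_frame=round(self.sync.stop_frame * scale),
        )

    def phase_labels(self) -> np.ndarray:
        """Per-frame subtask index 1..9 (0 outside the trial)."""
        labels = np.zeros(self.n_frames, dtype=int)
        for k in range(9):
            labels[self.boundary_frames[k] : self.boundary_frames[k + 1]] = k + 1
        return labels


def _build_phases(config: TrialConfig):
    """(duration, x(u), y(u)) closures for each scripted phase.

    The last ``transfer_blend_m`` of the vertical rise is carried into the
    first walking metre (and mirrored before sitting), as real subjects
    start stepping before the trunk is fully upright.  This keeps the
    walking subtask intervals free of stationary transfer dwell, so their
    mean speeds scale linearly with the scripted walking speed.
    """
    off = config.seated_offset_m
    y_sit, y_std = config.seated_com_m, config.stand_com_m
    blend = config.transfer_blend_m
    if not 0.0 < blend < (y_std - y_sit):
        raise InvalidConfigError("transfer_blend_m must lie in (0, rise height)")
    depth = config.turn_depth_m
    x_entry = config.walkway_m - depth
    s2, s3, s4 = config.walk_out_speeds_ms
    s6, s7, s8 = config.walk_back_speeds_ms
    marks = np.arange(1.0, config.walkway_m)  # 1, 2 for a 3 m walkway
    if marks.size < 2 or x_entry <= marks[-1]:
        raise InvalidConfigError("turn depth leaves no room for the last walkway metre")

    def const(v):
        return lambda u, v=v: np.full_like(np.asarray(u, dtype=float), v)

    def lerp(a, b):
        return lambda u, a=a, b=b: a + (b - a) * np.asarray(u, dtype=float)

    phases = [
        (config.lead_s, const(off), const(y_sit)),
        (
            config.sit_to_stand_s,
            lambda u: off * (1.0 - _smoothstep(u)),
            lambda u: y_sit + (y_std - blend - y_sit) * _smoothstep(u),
        ),
        (
            1.0 / s2,
            lerp(0.0, 1.0),
            lambda u: y_std - blend + blend * _smoothstep(u),
        ),
        (1.0 / s3, lerp(1.0, 2.0), const(y_std)),
        ((x_entry - 2.0) / s4, lerp(2.0, x_entry), const(y_std)),
        (
            config.turn_s,
            lambda u: config.walkway_m
            - depth * (1.0 + np.cos(2.0 * np.pi * np.asarray(u, dtype=float))) / 2.0,
            const(y_std),
        ),
        ((x_entry - 2.0) / s6, lerp(x_entry, 2.0), const(y_std)),
        (1.0 / s7, lerp(2.0, 1.0), const(y_std)),
        (
            1.0 / s8,
            lerp(1.0, 0.0),
            lambda u: y_std - blend * _smoothstep(u),
        ),
        (
            config.stand_to_sit_s,
            lambda u: off * _smoothstep(u),
            lambda u: y_std - blend - (y_std - blend - y_sit) * _smoothstep(u),
        ),
        (config.tail_s, const(off), const(y_sit)),
    ]
    return phases


def simulate_trajectory(
    config: TrialConfig, params: SegmentationParams = SegmentationParams()
) -> GroundTruth:
    """Script the COM path and derive frame-level ground truth.

    True subtask boundaries apply the same rule definitions as the
    analysis pipeline (stand-height band, metre-mark sign changes, peak
    turn margin) to the *noise-free* trajectory sampled at the video rate,
    so downstream comparisons isolate imaging error.  True mean speeds are
    path length / duration over each boundary interval, integrated on the
    dense grid.
    """
    phases = _build_phases(config)
    durations = [d for d, _, _ in phases]
    knots = np.concatenate([[0.0], np.cumsum(durations)])
    total_s = float(knots[-1])

    t_dense = np.union1d(np.arange(0.0, total_s, 1.0 / _DENSE_HZ), knots)
    x_dense = np.empty_like(t_dense)
    y_dense = np.empty_like(t_dense)
    for k, (dur, fx, fy) in enumerate(phases):
        sel = (t_dense >= knots[k]) & (t_dense <= knots[k + 1])
        u = (t_dense[sel] - knots[k]) / dur
        x_dense[sel] = fx(u)
        y_dense[sel] = fy(u)

    fps = config.fps_video
    n_frames = int(math.floor(total_s * fps)) + 1
    start_frame = round(config.lead_s * fps)
    stop_frame = round((total_s - config.tail_s) * fps)
    sync = SyncEvents(start_frame=start_frame, stop_frame=stop_frame)

    t_frames = np.arange(n_frames) / fps
    track = CentroidTrack(
        x_m=np.interp(t_frames, t_dense, x_dense),
        y_m=np.interp(t_frames, t_dense, y_dense),
        fps=fps,
    )
    segments = segment(track, None, sync, params)
    boundaries = segments.starts + (segments.ends[-1],)

    true_speeds = []
    for k in range(9):
        t_a, t_b = boundaries[k] / fps, boundaries[k + 1] / fps
        coord = y_dense if k in (0, 8) else x_dense
        sel = (t_dense >= t_a) & (t_dense <= t_b)
        grid_t = np.concatenate([[t_a], t_dense[sel], [t_b]])
        grid_c = np.interp(grid_t, t_dense, coord)
        path = float(np.abs(np.diff(grid_c)).sum())
        true_speeds.append(path / (t_b - t_a))

    return GroundTruth(
        config=config,
        t_dense=t_dense,
        x_dense=x_dense,
        y_dense=y_dense,
        sync=sync,
        boundary_frames=tuple(boundaries),
        true_speeds=tuple(true_speeds),
        n_frames=n_frames,
    )


def _silhouette_layout(config: TrialConfig, model: CalibrationModel, x_m: float, y_m: float):
    """Continuous pixel-space placement of torso rectangle and head disc.

    Returns (u_c, v_bottom, w_px, torso_h_px, head centre, radii) such that
    the analytic centroid of the composite shape is exactly the pixel image
    of the scripted COM.
    """
    mpp_x, mpp_y = model.one_pixel_x_m, model.one_pixel_y_m
    u_c = model.origin_u_px + model.x_sign * x_m / mpp_x
    v_c = model.floor_v_px - y_m / mpp_y
    h_px = (y_m / config.com_height_ratio) / mpp_y
    ru = config.head_radius_m / mpp_x
    rv = config.head_radius_m / mpp_y
    gap = config.head_gap_m / mpp_y
    torso_h = h_px - 2.0 * rv - gap
    if torso_h <= 0:
        raise InvalidConfigError("body too short for the configured head size")
    w_px = config.width_m / mpp_x
    area_t = w_px * torso_h
    area_h = math.pi * ru * rv
    # centroid height above the torso bottom edge
    c_rel = (area_t * torso_h / 2.0 + area_h * (torso_h + gap + rv)) / (area_t + area_h)
    v_bottom = v_c + c_rel
    v_head = v_bottom - torso_h - gap - rv
    return u_c, v_bottom, w_px, torso_h, v_head, ru, rv


def _rasterize_body(config: TrialConfig, model: CalibrationModel, x_m: float, y_m: float):
    u_c, v_bottom, w_px, torso_h, v_head, ru, rv = _silhouette_layout(config, model, x_m, y_m)
    if (
        u_c - w_px / 2 < 0
        or u_c + w_px / 2 > config.image_w - 1
        or v_head - rv < 0
        or v_bottom > config.image_h - 1
    ):
        raise InvalidConfigError(
            f"silhouette clipped by the frame at COM=({x_m:.2f}, {y_m:.2f}) m"
        )
    cols = np.arange(config.image_w, dtype=np.float64)
    rows = np.arange(config.image_h, dtype=np.float64)
    in_cols = np.abs(cols - u_c) <= w_px / 2.0
    in_rows = (rows > v_bottom - torso_h) & (rows <= v_bottom)
    mask = in_rows[:, None] & in_cols[None, :]
    mask |= ((cols[None, :] - u_c) / ru) ** 2 + ((rows[:, None] - v_head) / rv) ** 2 <= 1.0
    return mask


def render_background(config: TrialConfig) -> np.ndarray:
    """Static scene: flat grey plus the four calibration marker dots."""
    bg = np.full((config.image_h, config.image_w, 3), config.background_level, dtype=np.uint8)
    rows = np.arange(config.image_h, dtype=np.float64)
    cols = np.arange(config.image_w, dtype=np.float64)
    for u, v in (config.m1_px, config.m2_px, config.m3_px, config.m4_px):
        dot = (cols[None, :] - u) ** 2 + (rows[:, None] - v) ** 2 <= 9.0
        bg[dot] = config.marker_level
    return bg


def render_frames(gt: GroundTruth, config: TrialConfig | None = None):
    """Yield uint8 RGB frames for the whole trial (lazily, one at a time).

    Salt-and-pepper noise, when enabled, uses an independent
    counter-seeded stream per frame so frames are reproducible in any
    access order.
    """
    config = config or gt.config
    model = config.calibration()
    # fail fast if the standing body would leave the frame anywhere on the walkway
    for x_probe in (0.0, config.walkway_m):
        _rasterize_body(config, model, x_probe, config.stand_com_m)
    bg = render_background(config)
    x_f, y_f = gt.frame_com()
    for i in range(gt.n_frames):
        frame = bg.copy()
        mask = _rasterize_body(config, model, float(x_f[i]), float(y_f[i]))
        frame[mask] = config.body_level
        if config.noise_salt_pepper > 0:
            rng = np.random.default_rng([config.seed, _STREAM_VIDEO_NOISE, i])
            noisy = rng.random((config.image_h, config.image_w)) < config.noise_salt_pepper
            values = rng.integers(0, 2, size=int(noisy.sum())) * 255
            frame[noisy] = values[:, None].astype(np.uint8)
        yield frame


def simulate_mocap(gt: GroundTruth, config: TrialConfig | None = None) -> MarkerTrack3D:
    """Four pelvis markers around the true COM at the mocap rate.

    Axis convention: 0 = forward (walkway), 1 = lateral, 2 = up.  ASIS
    markers sit ``marker_ap_m`` ahead of the COM and PSIS behind; right
    markers are ``-marker_lateral_m`` and left ``+marker_lateral_m``.
    Symmetric offsets cancel in the four-marker mean.
    """
    config = config or gt.config
    fs = config.fs_mocap
    total_s = float(gt.t_dense[-1])
    n = int(math.floor(total_s * fs)) + 1
    times = np.arange(n) / fs
    x, y = gt.com_at(times)
    ap, lat = config.marker_ap_m, config.marker_lateral_m
    # marker order matches mocap.MARKER_NAMES: R_ASIS, L_ASIS, R_PSIS, L_PSIS
    offsets = np.array(
        [
            [ap, -lat, 0.0],
            [ap, lat, 0.0],
            [-ap, -lat, 0.0],
            [-ap, lat, 0.0],
        ]
    )
    coords = np.zeros((n, 4, 3))
    coords[:, :, 0] = x[:, None] + offsets[None, :, 0]
    coords[:, :, 1] = offsets[None, :, 1]
    coords[:, :, 2] = y[:, None] + offsets[None, :, 2]
    if config.mocap_noise_sd_m > 0:
        rng = np.random.default_rng([config.seed, _STREAM_MOCAP_NOISE])
        coords = coords + rng.normal(0.0, config.mocap_noise_sd_m, size=coords.shape)
    return MarkerTrack3D(coords=coords, fs=fs)


def simulate_paired(
    rho: float,
    n: int,
    sd_a: float = 1.0,
    sd_b: float = 1.0,
    seed: int = 0,
    mean_a: float = 0.0,
    mean_b: float = 0.0,
) -> PairedTable:
    """Bivariate-normal paired samples with correlation ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho must lie in [-1, 1], got {rho}")
    if n < 3:
        raise InvalidParameterError(f"need n >= 3, got {n}")
    rng = np.random.default_rng([seed, _STREAM_PAIRED])
    z1, z2 = rng.standard_normal((2, n))
    a = mean_a + sd_a * z1
    b = mean_b + sd_b * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return PairedTable(value_a=a, value_b=b)


def random_trial_config(seed: int, condition: str = "comfortable", **overrides) -> TrialConfig:
    """Draw a plausible per-subject trial config for a speed condition.

    Comfortable-like walks are ~1.0-1.2 m/s, fast-like ~1.3-1.5 m/s, with
    correspondingly quicker chair transfers and turns.
    """
    condition_tag = {"comfortable": 0, "fast": 1}.get(condition)
    if condition_tag is None:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    rng = np.random.default_rng([seed, 17, condition_tag])
    if condition == "comfortable":
        lo, hi = 1.0, 1.2
        sts = rng.uniform(1.1, 1.5)
        turn_s = rng.uniform(1.4, 1.8)
    elif condition == "fast":
        lo, hi = 1.3, 1.5
        sts = rng.uniform(0.8, 1.1)
        turn_s = rng.uniform(1.0, 1.4)
    walk_out = tuple(rng.uniform(lo, hi, size=3).round(4))
    walk_back = tuple(rng.uniform(lo, hi, size=3).round(4))
    return TrialConfig(
        sit_to_stand_s=round(float(sts), 4),
        walk_out_speeds_ms=walk_out,
        turn_s=round(float(turn_s), 4),
        walk_back_speeds_ms=walk_back,
        stand_to_sit_s=round(float(rng.uniform(1.1, 1.6)), 4),
        seed=seed,
        **overrides,
    )
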
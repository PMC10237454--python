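"""Shared fixtures: a small fast camera geometry and cached rendered trials."""

from __future__ import annotations

import numpy as np
import pytest

from tugspeed.pipeline import analyze_frames
from tugspeed.synthetic import TrialConfig, render_background, render_frames, simulate_trajectory

# 320x180 camera: 3 m = 250 px horizontally, 0.5 m = 40 px vertically.
SMALL_CAMERA = dict(
    image_w=320,
    image_h=180,
    m1_px=(280.0, 165.0),
    m2_px=(30.0, 165.0),
    m3_px=(15.0, 165.0),
    m4_px=(15.0, 125.0),
)


@pytest.fixture(scope="session")
def small_config() -> TrialConfig:
    return TrialConfig(**SMALL_CAMERA)


@pytest.fixture(scope="session")
def small_gt(small_config):
    return simulate_trajectory(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_config, small_gt):
    """Full pipeline result on the small noiseless trial (rendered once)."""
    return analyze_frames(
        render_frames(small_gt),
        render_background(small_config),
        small_config.marker_set(),
        small_gt.sync,
        fps=small_config.fps_video,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
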
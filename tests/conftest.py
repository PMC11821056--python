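"""Shared fixtures and helpers for the wormflow test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wormflow.config import SimConfig
from wormflow.intra import Tracklet
from wormflow.synthetic import WormState, render_worm, simulate


def straight_worm(x: float, y: float, heading: float = 0.0, *,
                  worm_id: int = 1, length: float = 85.0,
                  width: float = 12.0, phase: float = 0.0,
                  gray: float = 60.0) -> WormState:
    """A worm state with explicit pose, defaulting to the standard geometry."""
    return WormState(id=worm_id, centre=(x, y), heading=heading, phase=phase,
                     length=length, width=width, speed=4.0, gray=gray)


def worm_frame(states, shape=(200, 200), background=200) -> np.ndarray:
    """Render worm states onto a uniform background (no noise)."""
    canvas = np.full(shape, background, dtype=np.uint8)
    for s in states:
        render_worm(s, canvas)
    return canvas


def make_tracklet(tid: int, t_start: int, t_end: int, *,
                  first_pos=(0.0, 0.0), last_pos=None, velocity=(1.0, 0.0),
                  appearance=None) -> Tracklet:
    """A minimal tracklet for flow-graph tests."""
    if last_pos is None:
        span = t_end - t_start
        last_pos = (first_pos[0] + velocity[0] * span,
                    first_pos[1] + velocity[1] * span)
    frames = list(range(t_start, t_end + 1))
    n = len(frames)
    xs = np.linspace(first_pos[0], last_pos[0], n)
    ys = np.linspace(first_pos[1], last_pos[1], n)
    positions = [(float(x), float(y)) for x, y in zip(xs, ys)]
    boxes = [(int(x), int(y), 10, 10) for x, y in positions]
    return Tracklet(id=tid, frames=frames, positions=positions, boxes=boxes,
                    appearance=appearance, velocity=tuple(velocity),
                    t_start=t_start, t_end=t_end)


def gt_rows(video):
    """Flatten a SyntheticVideo's ground truth into (frame, id, bbox) rows."""
    return [(rec.frame, rec.id, tuple(float(v) for v in rec.bbox))
            for rec in video.gt_tracks]


@pytest.fixture(scope="session")
def small_video():
    """A 3-worm, collision-free clip shared by detection/intra tests."""
    cfg = SimConfig(n_worms=3, n_frames=20, frame_size=(300, 300),
                    collision_rate=0.0, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def crossing_frame():
    """Two worms whose centrelines cross in an X, plus their solo states."""
    a = straight_worm(100, 100, heading=math.pi / 4, worm_id=1)
    b = straight_worm(100, 100, heading=-math.pi / 4, worm_id=2, gray=70.0)
    return worm_frame([a, b]), (a, b)
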
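"""Synthetic multi-worm videos with exact ground truth.

Worms are modelled as inextensible centrelines of fixed arc length whose
curvature varies sinusoidally along the body, kappa(s) = A sin(2*pi*s/lambda
+ phase); advancing the phase produces the familiar crawling undulation.
The centreline is rasterized and dilated to a ~3 px body stroke so single
worms occupy 150-250 px of a frame, matching the imaging scale the detector's
default area threshold assumes (worms ~85 px long within a ~12 px envelope,
dark on a bright background).

Collisions do not occur by chance: a configurable number of worm pairs is
steered toward a common waypoint so short clips reliably contain touching
worms, while all other pairs are kept apart by an overlap veto.  Ground
truth records every worm in every frame, including during collisions.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import binary_dilation

from .config import ConfigError, SimConfig

__all__ = [
    "WormState", "GTRecord", "SyntheticVideo",
    "render_worm", "worm_mask", "simulate", "write_gt", "read_gt",
    "write_frames",
]


@dataclass
class WormState:
    """Kinematic state of one worm at one frame."""

    id: int
    centre: tuple[float, float]   # (x, y) px
    heading: float                # rad
    phase: float                  # rad, body-wave phase in [0, 2*pi)
    length: float                 # px
    width: float                  # px, undulation envelope
    speed: float                  # px/frame
    gray: float = 60.0            # mean body gray level
    phase_speed: float = 0.8      # rad/frame

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.speed < 0:
            raise ConfigError("worm geometry/speed invalid")
        self.phase %= 2 * math.pi


@dataclass
class GTRecord:
    """Ground truth for one worm in one frame (0-based pixel coordinates)."""

    frame: int
    id: int
    bbox: tuple[int, int, int, int]      # (left, top, w, h)
    centroid: tuple[float, float]        # (x, y)
    mask: np.ndarray                     # bool crop, shape (h, w) of bbox


@dataclass
class SyntheticVideo:
    frames: list[np.ndarray]
    gt_tracks: list[GTRecord]
    fps: float = 4.0
    seed: int = 0

    def gt_by_frame(self) -> dict[int, list[GTRecord]]:
        out: dict[int, list[GTRecord]] = {}
        for rec in self.gt_tracks:
            out.setdefault(rec.frame, []).append(rec)
        return out


# --------------------------------------------------------------------------
# body geometry

_N_SAMPLES = 256  # centreline integration resolution


def centreline_points(state: WormState) -> np.ndarray:
    """Integrate the curvature model into (x, y) centreline samples.

    The tangent angle at the body midpoint equals ``state.heading`` and the
    midpoint sits at ``state.centre``, so heading and centre describe the
    worm as a whole rather than its head.
    """
    L = state.length
    s = np.linspace(0.0, L, _N_SAMPLES)
    ds = s[1] - s[0]
    # curvature amplitude from the requested lateral envelope:
    # a sinusoidal tangent perturbation of amplitude A produces lateral
    # excursions ~ A * (lambda / 2*pi)**2, so invert that relation.
    lam = min(state.length * 0.7, 60.0)
    half_env = max(state.width - 3.0, 1.0) / 2.0
    amp = half_env / (lam / (2 * math.pi)) ** 2
    kappa = amp * np.sin(2 * math.pi * s / lam + state.phase)
    theta = np.cumsum(kappa) * ds
    theta -= theta[_N_SAMPLES // 2]
    theta += state.heading
    x = np.cumsum(np.cos(theta)) * ds
    y = np.cumsum(np.sin(theta)) * ds
    x -= x[_N_SAMPLES // 2]
    y -= y[_N_SAMPLES // 2]
    return np.stack([state.centre[0] + x, state.centre[1] + y], axis=1)


def worm_mask(state: WormState, shape: tuple[int, int],
              body_radius: int = 1) -> np.ndarray:
    """Rasterize the worm body into a boolean mask (off-canvas parts clipped)."""
    pts = centreline_points(state)
    rc = np.round(pts[:, ::-1]).astype(int)  # (row, col)
    keep = ((rc[:, 0] >= 0) & (rc[:, 0] < shape[0])
            & (rc[:, 1] >= 0) & (rc[:, 1] < shape[1]))
    mask = np.zeros(shape, dtype=bool)
    if not keep.any():
        return mask
    mask[rc[keep, 0], rc[keep, 1]] = True
    if body_radius > 0:
        yy, xx = np.mgrid[-body_radius:body_radius + 1,
                          -body_radius:body_radius + 1]
        footprint = np.abs(yy) + np.abs(xx) <= body_radius
        mask = binary_dilation(mask, structure=footprint)
    return mask


def render_worm(state: WormState, canvas: np.ndarray,
                body_radius: int = 1) -> np.ndarray:
    """Paint one worm onto ``canvas`` (uint8 grayscale), darkest-wins blending.

    Returns the canvas; portions outside the frame are clipped silently.
    """
    mask = worm_mask(state, canvas.shape, body_radius)
    canvas[mask] = np.minimum(canvas[mask], np.uint8(round(state.gray)))
    return canvas


def _mask_record(frame_idx: int, worm_id: int, mask: np.ndarray) -> GTRecord | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    top, left = int(rows.min()), int(cols.min())
    h = int(rows.max()) - top + 1
    w = int(cols.max()) - left + 1
    centroid = (float(cols.mean()), float(rows.mean()))
    return GTRecord(frame=frame_idx, id=worm_id, bbox=(left, top, w, h),
                    centroid=centroid, mask=mask[top:top + h, left:left + w].copy())


# --------------------------------------------------------------------------
# simulation


@dataclass
class _CollisionEvent:
    pair: tuple[int, int]
    t_start: int          # first frame of steering
    t_meet: int           # frame at which centres should coincide
    touched_frames: int = 0
    done: bool = False


def _initial_states(cfg: SimConfig, rng: np.random.Generator) -> list[WormState]:
    H, W = cfg.frame_size
    margin = cfg.worm_length_px / 2 + 5
    states: list[WormState] = []
    min_sep = cfg.worm_length_px * 1.3
    attempts = 0
    while len(states) < cfg.n_worms:
        attempts += 1
        if attempts > 10000:
            raise ConfigError("cannot place worms without overlap; frame too small")
        x = rng.uniform(margin, W - margin)
        y = rng.uniform(margin, H - margin)
        if any(math.hypot(x - s.centre[0], y - s.centre[1]) < min_sep
               for s in states):
            continue
        states.append(WormState(
            id=len(states) + 1,
            centre=(x, y),
            heading=rng.uniform(0, 2 * math.pi),
            phase=rng.uniform(0, 2 * math.pi),
            length=cfg.worm_length_px * rng.uniform(0.95, 1.05),
            width=cfg.worm_width_px,
            speed=cfg.speed_px * rng.uniform(0.8, 1.2),
            gray=cfg.worm_gray + rng.uniform(-cfg.gray_jitter, cfg.gray_jitter),
            phase_speed=cfg.phase_speed * rng.uniform(0.9, 1.1),
        ))
    return states


def _schedule_events(cfg: SimConfig, rng: np.random.Generator) -> list[_CollisionEvent]:
    n_events = int(round(cfg.collision_rate * cfg.n_frames / 100.0))
    if n_events == 0 or cfg.n_worms < 2:
        return []
    approach = min(25, max(3, cfg.n_frames // 3))  # steering frames before meeting
    events = []
    # spread meeting times over the usable span; randomize pair choice
    lo = approach + 2
    hi = max(cfg.n_frames - 3, lo + 1)
    meets = np.sort(rng.integers(lo, hi, size=n_events))
    for t_meet in meets:
        a, b = rng.choice(cfg.n_worms, size=2, replace=False)
        events.append(_CollisionEvent(
            pair=(int(a), int(b)),
            t_start=int(t_meet) - approach,
            t_meet=int(t_meet),
        ))
    return events


def _steer_towards(state: WormState, target: tuple[float, float],
                   max_turn: float = 0.35) -> None:
    want = math.atan2(target[1] - state.centre[1], target[0] - state.centre[0])
    diff = (want - state.heading + math.pi) % (2 * math.pi) - math.pi
    state.heading += float(np.clip(diff, -max_turn, max_turn))


def simulate(config: SimConfig) -> SyntheticVideo:
    """Run the worm simulation and render every frame.

    Deterministic: identical configs (including seed) yield bit-identical
    frames and ground truth.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_size
    states = _initial_states(config, rng)
    events = _schedule_events(config, rng)
    # reflect before any part of the body can leave the frame: a clipped
    # mask would make the ground-truth centroid jump discontinuously
    margin = config.worm_length_px * 1.05 / 2 + 8.0

    # static background impurities: tiny dark speckles well below min_area
    speckles = np.zeros((H, W), dtype=bool)
    for _ in range(config.n_speckles):
        r, c = rng.integers(2, H - 2), rng.integers(2, W - 2)
        rad = int(rng.integers(1, 3))
        speckles[max(r - rad, 0):r + rad + 1, max(c - rad, 0):c + rad + 1] = True

    frames: list[np.ndarray] = []
    gt: list[GTRecord] = []
    masks = [worm_mask(s, (H, W), config.body_radius_px) for s in states]

    active: set[int] = set(range(len(states)))

    for t in range(config.n_frames):
        # --- advance kinematics
        prev = [WormState(**{**s.__dict__}) for s in states]
        prev_masks = [m.copy() for m in masks]
        steering_pairs: set[frozenset[int]] = set()
        for ev in events:
            if ev.done or not (ev.t_start <= t <= ev.t_meet + 40):
                continue
            a, b = ev.pair
            if a not in active or b not in active:
                ev.done = True
                continue
            pair_key = frozenset(ev.pair)
            steering_pairs.add(pair_key)
            overlap_now = bool((masks[a] & masks[b]).any())
            if overlap_now:
                ev.touched_frames += 1
            if ev.touched_frames >= 1 and not overlap_now and ev.touched_frames >= 3:
                ev.done = True  # they met and separated again
            elif not overlap_now and ev.touched_frames == 0 and t <= ev.t_meet + 40:
                # steer each worm toward its partner's current centre
                _steer_towards(states[a], states[b].centre)
                _steer_towards(states[b], states[a].centre)

        for i in list(active):
            s = states[i]
            s.heading += rng.normal(0.0, config.heading_sigma)
            s.phase = (s.phase + s.phase_speed) % (2 * math.pi)
            nx = s.centre[0] + s.speed * math.cos(s.heading)
            ny = s.centre[1] + s.speed * math.sin(s.heading)
            if config.boundary == "reflect":
                if nx < margin or nx > W - margin:
                    s.heading = math.pi - s.heading
                    nx = float(np.clip(nx, margin, W - margin))
                if ny < margin or ny > H - margin:
                    s.heading = -s.heading
                    ny = float(np.clip(ny, margin, H - margin))
            s.centre = (nx, ny)
            if config.boundary == "exit" and not (
                    -s.length < nx < W + s.length and -s.length < ny < H + s.length):
                active.discard(i)

        for i in active:
            masks[i] = worm_mask(states[i], (H, W), config.body_radius_px)

        # --- contact veto for pairs that are not in a scheduled event;
        # "contact" includes a small clearance so that near-misses cannot
        # be merged into one blob by the detector's morphological closing
        yy, xx = np.mgrid[-3:4, -3:4]
        clearance = (yy * yy + xx * xx) <= 9  # euclidean radius 3

        def _touch(ma: np.ndarray, mb: np.ndarray) -> bool:
            if (ma & mb).any():
                return True
            return bool((binary_dilation(ma, structure=clearance) & mb).any())

        idx = sorted(active)
        for _ in range(len(idx) + 1):
            changed = False
            for ii, a in enumerate(idx):
                for b in idx[ii + 1:]:
                    if frozenset((a, b)) in steering_pairs:
                        continue
                    reach = (states[a].length + states[b].length) / 2 + 12
                    if math.hypot(states[a].centre[0] - states[b].centre[0],
                                  states[a].centre[1] - states[b].centre[1]) > reach:
                        continue
                    if not _touch(masks[a], masks[b]):
                        continue
                    if _touch(prev_masks[a], prev_masks[b]):
                        # already in contact before this step (e.g. an event
                        # just ended mid-overlap): let them separate freely
                        continue

                    def _revert(w: int, other: int) -> None:
                        away = math.atan2(
                            prev[w].centre[1] - prev[other].centre[1],
                            prev[w].centre[0] - prev[other].centre[0])
                        states[w] = WormState(**{**prev[w].__dict__})
                        states[w].heading = away + rng.normal(0.0, 0.2)
                        masks[w] = prev_masks[w]

                    # revert only the worm whose revert alone removes the
                    # contact, so a worm another walks into keeps moving
                    if not _touch(prev_masks[a], masks[b]):
                        _revert(a, b)
                    elif not _touch(masks[a], prev_masks[b]):
                        _revert(b, a)
                    else:
                        _revert(a, b)
                        _revert(b, a)
                    changed = True
            if not changed:
                break

        # --- render
        frame = np.full((H, W), config.background_gray, dtype=float)
        frame[speckles] = config.worm_gray
        for i in active:
            m = masks[i]
            frame[m] = np.minimum(frame[m], states[i].gray)
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, size=(H, W))
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))

        for i in active:
            rec = _mask_record(t, states[i].id, masks[i])
            if rec is not None:
                gt.append(rec)

    return SyntheticVideo(frames=frames, gt_tracks=gt, fps=4.0, seed=config.seed)


# --------------------------------------------------------------------------
# I/O


def write_gt(video: SyntheticVideo, path: str | Path) -> None:
    """Write ground truth in MOTChallenge CSV layout.

    Columns: frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z
    with 1-based frame indices and pixel coordinates, conf = 1, z = -1.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rec in video.gt_tracks:
            left, top, w, h = rec.bbox
            writer.writerow([
                rec.frame + 1, rec.id, left + 1, top + 1, w, h, 1,
                round(rec.centroid[0] + 1, 2), round(rec.centroid[1] + 1, 2), -1,
            ])


def read_gt(path: str | Path) -> list[tuple[int, int, tuple[float, float, float, float]]]:
    """Read a MOTChallenge CSV into (frame0, id, (left0, top0, w, h)) rows."""
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            try:
                frame, oid = int(float(row[0])), int(float(row[1]))
                left, top, w, h = (float(v) for v in row[2:6])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed CSV row at line {lineno}") from exc
            out.append((frame - 1, oid, (left - 1, top - 1, w, h)))
    return out


def write_frames(video: SyntheticVideo, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded PNGs: frame_000001.png, ..."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(video.frames, start=1):
        p = out_dir / f"frame_{t:06d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
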
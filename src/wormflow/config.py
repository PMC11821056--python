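"""Configuration objects for every pipeline stage.

All tunables live in small dataclasses, one per stage, grouped into a
:class:`PipelineConfig`.  A YAML file with the same nesting can override any
default; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates a stage invariant."""


@dataclass
class SimConfig:
    """Synthetic-video generator settings.

    The defaults emulate the imaging regime the tracker is designed for:
    dark worms (~85 px long, undulation envelope ~12 px wide, body area
    150-250 px) crawling at ~4 px/frame on a uniform bright background,
    recorded at ~4 fps.
    """

    n_worms: int = 10
    n_frames: int = 200
    frame_size: tuple[int, int] = (512, 512)  # (H, W)
    worm_length_px: float = 85.0
    worm_width_px: float = 12.0      # undulation envelope, not body stroke
    collision_rate: float = 5.0      # expected engineered collisions / 100 frames
    background_gray: int = 200
    worm_gray: int = 60
    noise_sigma: float = 2.0
    seed: int = 0
    # secondary knobs (kept out of the headline signature)
    speed_px: float = 4.0            # mean crawl speed, px/frame (~0.2 mm/s @ 4 fps)
    body_radius_px: int = 1          # dilation radius of the centreline stroke
    undulation_wavelength: float = 60.0
    phase_speed: float = 0.8         # rad/frame body-wave advance
    heading_sigma: float = 0.08      # rad/frame heading random walk
    gray_jitter: float = 10.0        # per-worm mean gray offset, uniform +/- this
    n_speckles: int = 8              # static background impurities (sub-min_area)
    boundary: str = "reflect"        # "reflect" or "exit"

    def __post_init__(self) -> None:
        if self.n_worms <= 0 or self.n_frames <= 0:
            raise ConfigError("n_worms and n_frames must be positive")
        if self.worm_gray >= self.background_gray:
            raise ConfigError("worms must be darker than the background")
        if min(self.frame_size) <= 0:
            raise ConfigError("frame_size must be positive")
        if self.worm_length_px <= 0 or self.worm_width_px <= 0:
            raise ConfigError("worm geometry must be positive")
        if self.collision_rate < 0 or self.noise_sigma < 0 or self.speed_px < 0:
            raise ConfigError("rates, noise and speed must be non-negative")
        if self.boundary not in ("reflect", "exit"):
            raise ConfigError("boundary must be 'reflect' or 'exit'")
        self.frame_size = tuple(self.frame_size)  # type: ignore[assignment]


@dataclass
class DetectionConfig:
    """Binarization and blob-extraction settings.

    ``t_area`` is the collision-judgement area threshold: a blob whose area
    strictly exceeds it is treated as several touching worms.
    """

    t_area: int = 300
    min_area: int = 50
    adaptive_block: int = 51   # local-mean window (odd)
    adaptive_offset: float = 15.0  # gray levels below local mean to call foreground
    morph_radius: int = 1
    invert: bool = False       # set for bright worms on a dark background
    drop_border: bool = False  # drop blobs touching the frame border

    def __post_init__(self) -> None:
        if not (self.t_area > self.min_area > 0):
            raise ConfigError("need t_area > min_area > 0")
        if self.adaptive_block % 2 == 0 or self.adaptive_block < 3:
            raise ConfigError("adaptive_block must be odd and >= 3")
        if self.morph_radius < 0:
            raise ConfigError("morph_radius must be >= 0")


@dataclass
class SkeletonConfig:
    """Collision-splitting settings for the improved skeleton method."""

    connect_tol: float = 6.0     # px gap bridgeable through a removed branchpoint
    shared_tol: float = 0.25     # residual fraction above which sharing is tried
    min_segment_px: int = 3      # shorter post-split segments are thinning debris
    n_points: int = 10           # L resampled skeleton points per path

    def __post_init__(self) -> None:
        if self.connect_tol <= 0 or not (0 < self.shared_tol < 1):
            raise ConfigError("bad skeleton tolerances")
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")


@dataclass
class MatchParams:
    """Adjacent-frame gating: distance threshold, angle threshold, window."""

    dist_thr: float = 20.0              # px
    angle_thr: float = math.pi / 4      # rad
    window: int = 3                     # frames per trajectory fragment

    def __post_init__(self) -> None:
        if self.dist_thr <= 0:
            raise ConfigError("dist_thr must be positive")
        if not (0 < self.angle_thr <= math.pi / 2):
            raise ConfigError("angle_thr must lie in (0, pi/2]")
        if self.window < 2:
            raise ConfigError("window must be >= 2")


@dataclass
class CostConfig:
    """Network-flow cost model."""

    w_a: float = 0.5          # appearance weight
    w_v: float = 0.5          # velocity weight
    c_enter: float = 0.4
    c_exit: float = 0.4
    c_det: float = -0.6       # negative: a real fragment pays for itself
    # worms are detected in every frame (collisions are split, not dropped),
    # so fragment gaps come only from short chain breaks; long transition
    # edges would allow physically impossible jumps
    max_gap: int = 3          # frames bridgeable by a transition edge
    mask_size: int = 5        # M, grayscale sampling window (odd)
    n_skel: int = 10          # L skeleton points in the appearance vector
    sqrt_bhattacharyya: bool = False  # use sqrt(1 - BC) instead of 1 - BC
    interpolate_gaps: bool = True     # fill intra-trajectory frame gaps linearly

    def __post_init__(self) -> None:
        if abs(self.w_a + self.w_v - 1.0) > 1e-9:
            raise ConfigError("appearance and velocity weights must sum to 1")
        if self.max_gap < 1:
            raise ConfigError("max_gap must be >= 1")
        if self.mask_size < 1 or self.mask_size % 2 == 0:
            raise ConfigError("mask_size must be odd and >= 1")
        if self.n_skel < 2:
            raise ConfigError("n_skel must be >= 2")


@dataclass
class EvalConfig:
    """CLEAR-MOT scoring settings."""

    iou_thr: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.iou_thr <= 1):
            raise ConfigError("iou_thr must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """All stage configurations plus run-level bookkeeping."""

    simulate: SimConfig = field(default_factory=SimConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    intra: MatchParams = field(default_factory=MatchParams)
    flow: CostConfig = field(default_factory=CostConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    log_level: str = "INFO"


_SECTIONS = {
    "simulate": SimConfig,
    "detection": DetectionConfig,
    "skeleton": SkeletonConfig,
    "intra": MatchParams,
    "flow": CostConfig,
    "eval": EvalConfig,
}


def _build(cls: type, values: dict[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{where}': {sorted(unknown)}")
    return cls(**values)


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults, a YAML file, overrides.

    Precedence: ``overrides`` > file > defaults.  ``overrides`` uses the same
    nested-dict shape as the YAML file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        data = loaded
    for section, vals in (overrides or {}).items():
        if isinstance(vals, dict):
            data.setdefault(section, {}).update(vals)
        else:
            data[section] = vals

    cfg_kwargs: dict[str, Any] = {}
    for key, vals in data.items():
        if key in _SECTIONS:
            if not isinstance(vals, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            cfg_kwargs[key] = _build(_SECTIONS[key], vals, key)
        elif key in ("seed", "log_level"):
            cfg_kwargs[key] = vals
        else:
            raise ConfigError(f"unknown top-level config key: '{key}'")
    return PipelineConfig(**cfg_kwargs)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
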
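"""Intra-trajectory stage: per-frame detections -> trajectory fragments.

Non-colliding worms are linked frame to frame when their skeleton centres
fall within a distance gate and their body orientations within an angle
gate; among gate-passing candidates the total centre distance is minimized
by optimal bipartite assignment.  Colliding blobs are first split by the
improved skeleton method using the implicated worms' pre-collision skeleton
lengths, and the split detections then flow through the same matcher.
Chains of matches are cut into fixed-length windows (default three frames),
yielding the trajectory fragments that the network-flow stage associates
globally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import DetectionConfig, MatchParams, PipelineConfig, SkeletonConfig
from .detection import Blob, detect_frame
from .skeleton import (DegenerateSkeletonError, SkeletonPath, assign_segments,
                       longest_path_chain, path_descriptor, skeletonize_blob,
                       split_at_branchpoints)

__all__ = [
    "WormDetection", "Tracklet", "match_pair", "link_frame",
    "build_tracklets", "track_collision", "run_intra",
]

_BIG = 1e9


@dataclass
class WormDetection:
    """One worm observed in one frame."""

    frame: int
    path: SkeletonPath
    bbox: tuple[int, int, int, int]        # (left, top, w, h)
    appearance: np.ndarray | None = None   # L-vector of mean grays
    from_collision: bool = False
    blob_area: int = 0
    bound_chain_id: int | None = None      # chain whose prior produced this split

    @property
    def centre(self) -> tuple[float, float]:
        return self.path.centre

    @property
    def orientation(self) -> float:
        return self.path.orientation


@dataclass
class Tracklet:
    """A trajectory fragment: vertex of the network-flow graph."""

    id: int
    frames: list[int]
    positions: list[tuple[float, float]]
    boxes: list[tuple[int, int, int, int]]
    appearance: np.ndarray | None
    velocity: tuple[float, float]
    t_start: int
    t_end: int
    from_collision: bool = False

    @property
    def first_pos(self) -> tuple[float, float]:
        return self.positions[0]

    @property
    def last_pos(self) -> tuple[float, float]:
        return self.positions[-1]


def _fold_angle(a: float, b: float) -> float:
    """Undirected orientation difference, folded into [0, pi/2]."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def match_pair(det_t: SkeletonPath, det_t1: SkeletonPath,
               params: MatchParams) -> bool:
    """Adjacent-frame gate: centre distance and orientation change.

    Both comparisons are inclusive: a pair exactly on either threshold
    matches.
    """
    d = math.hypot(det_t1.centre[0] - det_t.centre[0],
                   det_t1.centre[1] - det_t.centre[1])
    dO = _fold_angle(det_t.orientation, det_t1.orientation)
    return d <= params.dist_thr and dO <= params.angle_thr


def link_frame(dets_t: list[WormDetection], dets_t1: list[WormDetection],
               params: MatchParams) -> list[tuple[int, int]]:
    """One-to-one matching between consecutive frames.

    Among all gate-passing pairs, the assignment minimizing total centre
    distance is chosen; ungated pairs are never matched.
    """
    if not dets_t or not dets_t1:
        return []
    cost = np.full((len(dets_t), len(dets_t1)), _BIG)
    for i, a in enumerate(dets_t):
        for j, b in enumerate(dets_t1):
            if match_pair(a.path, b.path, params):
                cost[i, j] = math.hypot(b.centre[0] - a.centre[0],
                                        b.centre[1] - a.centre[1])
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _BIG]


# --------------------------------------------------------------------------
# chain bookkeeping


@dataclass(eq=False)
class _Chain:
    id: int
    last_det: WormDetection
    last_frame: int
    buffer: list[WormDetection]
    centres: list[tuple[float, float]] = field(default_factory=list)
    prior_length: float | None = None     # frozen at collision onset
    in_collision: bool = False

    def velocity(self) -> tuple[float, float]:
        if len(self.centres) < 2:
            return (0.0, 0.0)
        (x0, y0), (x1, y1) = self.centres[-2], self.centres[-1]
        return (x1 - x0, y1 - y0)

    def predicted_centre(self) -> tuple[float, float]:
        vx, vy = self.velocity()
        x, y = self.centres[-1]
        return (x + vx, y + vy)


def _emit(chain: _Chain, out: list[Tracklet], next_id: list[int]) -> None:
    dets = chain.buffer
    if not dets:
        return
    frames = [d.frame for d in dets]
    positions = [d.centre for d in dets]
    span = frames[-1] - frames[0]
    if span > 0:
        vel = ((positions[-1][0] - positions[0][0]) / span,
               (positions[-1][1] - positions[0][1]) / span)
    else:
        vel = (0.0, 0.0)
    profiles = [d.appearance for d in dets if d.appearance is not None]
    app = np.mean(profiles, axis=0) if profiles else None
    out.append(Tracklet(
        id=next_id[0], frames=frames, positions=positions,
        boxes=[d.bbox for d in dets], appearance=app, velocity=vel,
        t_start=frames[0], t_end=frames[-1],
        from_collision=any(d.from_collision for d in dets),
    ))
    next_id[0] += 1
    chain.buffer = []


class _ChainTracker:
    """Links detections frame by frame and cuts chains into windows."""

    def __init__(self, params: MatchParams):
        self.params = params
        self.chains: list[_Chain] = []
        self.tracklets: list[Tracklet] = []
        self._next_tid = [0]
        self._next_cid = 0

    def active(self, frame_idx: int) -> list[_Chain]:
        return [c for c in self.chains if c.last_frame == frame_idx - 1]

    def step(self, frame_idx: int, dets: list[WormDetection]) -> None:
        act = self.active(frame_idx)
        matches = dict()
        # split detections carry the identity of the chain whose recorded
        # skeleton length produced them; honour it (distance-sane) so worm
        # identity survives the collision
        by_id = {c.id: c for c in act}
        bound_chains: set[int] = set()
        for j, det in enumerate(dets):
            c = by_id.get(det.bound_chain_id) if det.bound_chain_id is not None else None
            if c is not None and c.id not in bound_chains:
                d = math.hypot(det.centre[0] - c.centres[-1][0],
                               det.centre[1] - c.centres[-1][1])
                if d <= self.params.dist_thr:
                    matches[j] = c
                    bound_chains.add(c.id)
        free_act = [c for c in act if c.id not in bound_chains]
        free_js = [j for j in range(len(dets)) if j not in matches]
        prev = [c.last_det for c in free_act]
        for i, j in link_frame(prev, [dets[j] for j in free_js], self.params):
            matches[free_js[j]] = free_act[i]
        matched_ids = {id(c) for c in matches.values()}
        for c in act:
            if id(c) not in matched_ids:
                _emit(c, self.tracklets, self._next_tid)  # chain breaks
        for j, det in enumerate(dets):
            chain = matches.get(j)
            if chain is None:
                chain = _Chain(id=self._next_cid, last_det=det,
                               last_frame=frame_idx, buffer=[])
                self._next_cid += 1
                self.chains.append(chain)
            chain.last_det = det
            chain.last_frame = frame_idx
            chain.centres.append(det.centre)
            chain.buffer.append(det)
            if not det.from_collision:
                if chain.in_collision:
                    chain.in_collision = False
                    chain.prior_length = None
            if len(chain.buffer) >= self.params.window:
                _emit(chain, self.tracklets, self._next_tid)
        self.chains = [c for c in self.chains
                       if c.last_frame >= frame_idx - 1]

    def finish(self) -> list[Tracklet]:
        for c in sorted(self.chains, key=lambda c: c.id):
            _emit(c, self.tracklets, self._next_tid)
        self.chains = []
        return self.tracklets


def build_tracklets(all_dets: list[list[WormDetection]],
                    params: MatchParams) -> list[Tracklet]:
    """Chain per-frame detections into window-length trajectory fragments.

    Every detection ends up in exactly one tracklet; unmatched detections
    become singleton fragments.
    """
    tracker = _ChainTracker(params)
    for t, dets in enumerate(all_dets):
        tracker.step(t, dets)
    return tracker.finish()


# --------------------------------------------------------------------------
# per-blob detection builders


def _chain_bbox(chain: np.ndarray, shape: tuple[int, int],
                pad: int = 2) -> tuple[int, int, int, int]:
    top = max(int(chain[:, 0].min()) - pad, 0)
    left = max(int(chain[:, 1].min()) - pad, 0)
    bottom = min(int(chain[:, 0].max()) + pad, shape[0] - 1)
    right = min(int(chain[:, 1].max()) + pad, shape[1] - 1)
    return (left, top, right - left + 1, bottom - top + 1)


def _single_worm_detection(blob: Blob, skel_cfg: SkeletonConfig,
                           from_collision: bool = False) -> WormDetection | None:
    try:
        graph = skeletonize_blob(blob)
        segments = split_at_branchpoints(graph, skel_cfg.min_segment_px)
        if len(segments) == 1:
            chain = segments[0]
        else:  # coiled body or thinning spurs: take the main axis
            chain = longest_path_chain(graph)
        if len(chain) < 2:
            return None
        path = path_descriptor(chain, skel_cfg.n_points)
    except DegenerateSkeletonError:
        return None
    return WormDetection(frame=blob.frame, path=path, bbox=blob.bbox,
                         from_collision=from_collision, blob_area=blob.area)


def track_collision(blob: Blob, active_chains: list[_Chain],
                    skel_cfg: SkeletonConfig, params: MatchParams,
                    frame_shape: tuple[int, int]) -> list[WormDetection]:
    """Split a collided blob into per-worm detections.

    A chain is implicated when its constant-velocity predicted centre falls
    inside the blob's bounding box dilated by the distance gate.  With two
    or more implicated chains, the skeleton is split at its branchpoints and
    the segments are distributed using the chains' recorded pre-collision
    skeleton lengths; extra chains beyond the best two stay unresolved for
    this frame.  With fewer than two, the blob is treated as a single worm.
    """
    left, top, w, h = blob.bbox
    g = params.dist_thr
    implicated = []
    for c in active_chains:
        px, py = c.predicted_centre()
        if (left - g <= px <= left + w + g) and (top - g <= py <= top + h + g):
            implicated.append(c)
    if len(implicated) < 2:
        det = _single_worm_detection(blob, skel_cfg)
        return [det] if det is not None else []

    cx, cy = blob.centroid
    implicated.sort(key=lambda c: (math.hypot(c.predicted_centre()[0] - cx,
                                              c.predicted_centre()[1] - cy),
                                   c.id))
    pair = implicated[:2]
    priors = []
    for c in pair:
        if not c.in_collision or c.prior_length is None:
            c.prior_length = c.last_det.path.length
            c.in_collision = True
        priors.append((c.id, c.prior_length, c.centres[-1]))

    try:
        graph = skeletonize_blob(blob)
        segments = split_at_branchpoints(graph, skel_cfg.min_segment_px)
    except DegenerateSkeletonError:
        segments = []
    if not segments:
        det = _single_worm_detection(blob, skel_cfg)
        return [det] if det is not None else []

    assignment = assign_segments(segments, priors, skel_cfg)
    dets = []
    for wid in assignment.worm_ids:
        chain = assignment.assembled_chains.get(wid)
        if chain is None or len(chain) < 2:
            continue
        try:
            path = path_descriptor(chain, skel_cfg.n_points)
        except DegenerateSkeletonError:
            continue
        dets.append(WormDetection(
            frame=blob.frame, path=path,
            bbox=_chain_bbox(chain, frame_shape),
            from_collision=True, blob_area=blob.area,
            bound_chain_id=wid,
        ))
    if not dets:
        det = _single_worm_detection(blob, skel_cfg)
        return [det] if det is not None else []
    if len(dets) == 2:
        # near-equal prior lengths make the length-residual labelling
        # arbitrary; bind each split worm to the chain whose predicted
        # centre it continues, swapping labels when that is closer
        by_id = {c.id: c for c in pair}
        other = {pair[0].id: pair[1].id, pair[1].id: pair[0].id}
        keep = sum(_pred_dist(by_id[d.bound_chain_id], d) for d in dets)
        swap = sum(_pred_dist(by_id[other[d.bound_chain_id]], d) for d in dets)
        if swap < keep:
            a, b = dets
            a.bound_chain_id, b.bound_chain_id = b.bound_chain_id, a.bound_chain_id
    return dets


def _pred_dist(chain: _Chain, det: WormDetection) -> float:
    px, py = chain.predicted_centre()
    cx, cy = det.path.centre
    return math.hypot(px - cx, py - cy)


# --------------------------------------------------------------------------
# driver


def run_intra(frames: list[np.ndarray], cfg: PipelineConfig,
              collect_detections: bool = False):
    """Detection + collision splitting + windowed chaining over a video.

    Returns the list of tracklets; with ``collect_detections`` also the
    per-frame detections.
    """
    from .flow import appearance_profile  # local import: flow also types against us

    det_cfg: DetectionConfig = cfg.detection
    skel_cfg: SkeletonConfig = cfg.skeleton
    params: MatchParams = cfg.intra
    tracker = _ChainTracker(params)
    all_dets: list[list[WormDetection]] = []

    for t, frame in enumerate(frames):
        blobs = detect_frame(frame, t, det_cfg)
        active = tracker.active(t)
        dets: list[WormDetection] = []
        for blob in blobs:
            if blob.is_collided:
                dets.extend(track_collision(blob, active, skel_cfg, params,
                                            frame.shape))
            else:
                d = _single_worm_detection(blob, skel_cfg)
                if d is not None:
                    dets.append(d)
        for d in dets:
            d.appearance = appearance_profile(frame, d.path, cfg.flow.mask_size)
        tracker.step(t, dets)
        all_dets.append(dets)

    tracklets = tracker.finish()
    if collect_detections:
        return tracklets, all_dets
    return tracklets
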
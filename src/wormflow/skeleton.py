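"""Skeleton extraction and collision splitting.

A single worm thins to a simple 1-px path.  When two worms touch, their
merged blob thins to a skeleton with *branchpoints* (pixels with three or
more skeleton neighbours).  The splitting procedure removes the branchpoint
clusters, which cuts the skeleton into segments, then searches for the
combination of segments that best reassembles each worm: segment subsets
must be connectable end-to-end through the removed branchpoint sites, and
the chosen combination minimizes the total absolute difference between each
reassembled length and the worm's recorded pre-collision skeleton length.
A segment may be assigned to both worms (a shared stretch of body) when an
exclusive assignment leaves a worm's length residual above tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import skeletonize

from .config import SkeletonConfig
from .detection import Blob

__all__ = [
    "DegenerateSkeletonError", "SkeletonGraph", "SkeletonPath",
    "SegmentAssignment", "skeletonize_blob", "split_at_branchpoints",
    "assign_segments", "path_descriptor", "longest_path_chain",
    "chain_length",
]

_NBHD = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class DegenerateSkeletonError(ValueError):
    """Raised when a blob or chain is too small to carry a skeleton."""


@dataclass
class SkeletonGraph:
    """Pixel-level skeleton with 8-neighbour adjacency."""

    points: set[tuple[int, int]]                    # (row, col)
    adjacency: dict[tuple[int, int], list[tuple[int, int]]]
    branchpoints: set[tuple[int, int]]
    endpoints: set[tuple[int, int]]


@dataclass
class SkeletonPath:
    """Descriptor of one ordered skeleton chain.

    ``orientation`` is the undirected angle in [0, pi) of the line through
    the arc-length midpoint and the geometrically nearer endpoint; worm
    head/tail is not resolved so directions are folded.
    """

    ordered_pixels: np.ndarray    # (n, 2) of (row, col)
    length: float                 # px, diagonal steps count sqrt(2)
    centre: tuple[float, float]   # (x, y), lies on the chain
    orientation: float            # rad in [0, pi)
    resampled: np.ndarray         # (L, 2) of (x, y), evenly spaced by arc length


@dataclass
class SegmentAssignment:
    """Result of distributing post-split segments among colliding worms."""

    worm_ids: list[int]
    segments_per_worm: dict[int, list[int]]        # worm_id -> ordered segment idx
    assembled_chains: dict[int, np.ndarray]        # worm_id -> ordered (row, col)
    assembled_lengths: dict[int, float]
    shared_segments: list[int] = field(default_factory=list)
    residual: float = 0.0
    fallback: bool = False                          # nearest-centroid rescue used


# --------------------------------------------------------------------------
# graph construction


def _graph_from_mask(mask: np.ndarray, offset: tuple[int, int]) -> SkeletonGraph:
    rows, cols = np.nonzero(mask)
    pts = {(int(r) + offset[0], int(c) + offset[1]) for r, c in zip(rows, cols)}
    adjacency = {
        p: [q for dr, dc in _NBHD if (q := (p[0] + dr, p[1] + dc)) in pts]
        for p in pts
    }
    branch = {p for p, nb in adjacency.items() if len(nb) >= 3}
    ends = {p for p, nb in adjacency.items() if len(nb) == 1}
    return SkeletonGraph(points=pts, adjacency=adjacency,
                         branchpoints=branch, endpoints=ends)


def skeletonize_blob(blob: Blob) -> SkeletonGraph:
    """Thin a blob to its 1-px skeleton graph (global pixel coordinates)."""
    if blob.area < 3:
        raise DegenerateSkeletonError(f"blob of {blob.area} px has no skeleton")
    left, top = blob.bbox[0], blob.bbox[1]
    padded = np.pad(blob.mask, 1)
    skel = skeletonize(padded)
    return _graph_from_mask(skel, (top - 1, left - 1))


# --------------------------------------------------------------------------
# chains


def chain_length(chain: np.ndarray) -> float:
    """Arc length of an ordered pixel chain: 1 per axial, sqrt(2) per diagonal."""
    if len(chain) < 2:
        return 0.0
    steps = np.diff(np.asarray(chain, dtype=float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _trace_chain(points: set[tuple[int, int]],
                 adjacency: dict) -> np.ndarray:
    """Order a degree-<=2 component into a pixel chain (cycles are broken)."""
    sub = {p: [q for q in adjacency[p] if q in points] for p in points}
    ends = sorted(p for p, nb in sub.items() if len(nb) <= 1)
    start = ends[0] if ends else min(points)
    chain = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in sub[cur] if q not in seen]
        if not nxt:
            break
        cur = min(nxt)
        chain.append(cur)
        seen.add(cur)
    return np.array(chain, dtype=int)


def split_at_branchpoints(skel: SkeletonGraph,
                          min_segment_px: int = 3) -> list[np.ndarray]:
    """Delete branchpoint clusters and return the remaining ordered segments.

    The removal cluster is every branchpoint plus any skeleton pixel adjacent
    to two or more branchpoints, which suppresses 1-2 px stubs between nearby
    junctions.  Segments shorter than ``min_segment_px`` pixels are thinning
    artifacts and are dropped.  A branchpoint-free skeleton comes back as a
    single chain.
    """
    removal = set(skel.branchpoints)
    for p, nb in skel.adjacency.items():
        if p not in removal and sum(q in skel.branchpoints for q in nb) >= 2:
            removal.add(p)
    remaining = skel.points - removal
    segments: list[np.ndarray] = []
    unvisited = set(remaining)
    while unvisited:
        seed = min(unvisited)
        comp = {seed}
        stack = [seed]
        while stack:
            p = stack.pop()
            for q in skel.adjacency[p]:
                if q in unvisited and q not in comp:
                    comp.add(q)
                    stack.append(q)
        unvisited -= comp
        if len(comp) >= min_segment_px:
            segments.append(_trace_chain(comp, skel.adjacency))
    segments.sort(key=lambda c: (c[0][0], c[0][1]))
    return segments


def longest_path_chain(skel: SkeletonGraph) -> np.ndarray:
    """Longest endpoint-to-endpoint path: the body axis of a single worm.

    Double-BFS (weighted by step length) over the skeleton graph; tolerates
    small spurs that survive thinning.
    """
    if not skel.points:
        raise DegenerateSkeletonError("empty skeleton")

    def far(start):
        dist = {start: 0.0}
        parent = {start: None}
        frontier = [start]
        best = (0.0, start)
        while frontier:
            frontier.sort()
            nxt = []
            for p in frontier:
                for q in skel.adjacency[p]:
                    step = math.hypot(q[0] - p[0], q[1] - p[1])
                    if q not in dist or dist[p] + step < dist[q] - 1e-12:
                        dist[q] = dist[p] + step
                        parent[q] = p
                        nxt.append(q)
            frontier = nxt
        for p, d in sorted(dist.items()):
            if d > best[0] + 1e-12:
                best = (d, p)
        return best[1], parent

    a, _ = far(min(skel.points))
    b, parent = far(a)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return np.array(path[::-1], dtype=int)


# --------------------------------------------------------------------------
# descriptor


def path_descriptor(chain: np.ndarray, L: int = 10) -> SkeletonPath:
    """Compute length, midpoint, orientation, and L resampled points."""
    chain = np.asarray(chain, dtype=int)
    if len(chain) < 2:
        raise DegenerateSkeletonError("chain of < 2 px has no descriptor")
    steps = np.hypot(*np.diff(chain.astype(float), axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = float(cum[-1])
    mid_idx = int(np.argmin(np.abs(cum - total / 2)))
    centre_rc = chain[mid_idx]
    centre = (float(centre_rc[1]), float(centre_rc[0]))

    d0 = math.hypot(*(chain[0] - centre_rc))
    d1 = math.hypot(*(chain[-1] - centre_rc))
    near = chain[0] if d0 <= d1 else chain[-1]
    if (near == centre_rc).all():  # 2-px chains: midpoint is an endpoint
        near = chain[-1] if d0 <= d1 else chain[0]
    angle = math.atan2(near[0] - centre_rc[0], near[1] - centre_rc[1])
    orientation = angle % math.pi
    if abs(orientation - math.pi) < 1e-12:
        orientation = 0.0

    targets = np.linspace(0.0, total, L)
    rows = np.interp(targets, cum, chain[:, 0].astype(float))
    cols = np.interp(targets, cum, chain[:, 1].astype(float))
    resampled = np.stack([cols, rows], axis=1)  # (x, y)
    return SkeletonPath(ordered_pixels=chain, length=total, centre=centre,
                        orientation=orientation, resampled=resampled)


# --------------------------------------------------------------------------
# segment assignment (the dynamic matching step)


def _segment_ends(seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return seg[0].astype(float), seg[-1].astype(float)


def _chain_dp(segments: list[np.ndarray], connect_tol: float):
    """Best end-to-end chaining of every segment subset.

    Returns ``table[mask] = (gap, order)`` where ``order`` is a list of
    (segment_idx, flipped) pairs and ``gap`` the summed junction distances;
    subsets that cannot be chained within ``connect_tol`` are absent.
    Dynamic program over (subset, last segment, free endpoint).
    """
    n = len(segments)
    ends = [(_segment_ends(s)) for s in segments]

    def jump(i, ei, j, ej) -> float:
        return float(np.hypot(*(ends[i][ei] - ends[j][ej])))

    # dp[(mask, last, free_end)] = (gap, order)
    dp: dict[tuple[int, int, int], tuple[float, list]] = {}
    for i in range(n):
        for free in (0, 1):
            # entering endpoint is 1-free; flipped when we enter at index 1
            dp[(1 << i, i, free)] = (0.0, [(i, free == 0)])
    for mask in range(1, 1 << n):
        for i in range(n):
            if not mask & (1 << i):
                continue
            for free in (0, 1):
                cur = dp.get((mask, i, free))
                if cur is None:
                    continue
                gap, order = cur
                for j in range(n):
                    if mask & (1 << j):
                        continue
                    for enter in (0, 1):
                        g = jump(i, free, j, enter)
                        if g > connect_tol:
                            continue
                        key = (mask | (1 << j), j, 1 - enter)
                        cand = (gap + g, order + [(j, enter == 1)])
                        if key not in dp or cand[0] < dp[key][0] - 1e-12:
                            dp[key] = cand
    table: dict[int, tuple[float, list]] = {0: (0.0, [])}
    for (mask, _i, _f), (gap, order) in dp.items():
        if mask not in table or gap < table[mask][0] - 1e-12:
            table[mask] = (gap, order)
    return table


def _assemble(segments: list[np.ndarray], order: list[tuple[int, bool]]) -> np.ndarray:
    parts = [segments[i][::-1] if flip else segments[i] for i, flip in order]
    return np.concatenate(parts) if parts else np.empty((0, 2), dtype=int)


def _split_single_segment(seg: np.ndarray, priors, cfg: SkeletonConfig):
    """End-to-end contact: cut one chain at the interior point that best
    matches both recorded lengths (brute force over cut points)."""
    (id1, l1, _c1), (id2, l2, _c2) = priors[0], priors[1]
    steps = np.hypot(*np.diff(seg.astype(float), axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    best = None
    for k in range(1, len(seg) - 1):
        la, lb = cum[k], total - cum[k]
        for (ida, ta), (idb, tb) in (((id1, l1), (id2, l2)),
                                     ((id2, l2), (id1, l1))):
            resid = abs(la - ta) + abs(lb - tb)
            key = (resid, ida, k)
            if best is None or key < best[0]:
                best = (key, {ida: seg[:k + 1], idb: seg[k:]})
    (resid, _, _), chains = best
    return SegmentAssignment(
        worm_ids=[p[0] for p in priors],
        segments_per_worm={wid: [0] for wid in chains},
        assembled_chains=chains,
        assembled_lengths={wid: chain_length(ch) for wid, ch in chains.items()},
        shared_segments=[0],
        residual=float(resid),
    )


def _fallback_centroid(segments, priors) -> SegmentAssignment:
    per: dict[int, list[int]] = {p[0]: [] for p in priors}
    for i, seg in enumerate(segments):
        mid = seg[len(seg) // 2].astype(float)
        nearest = min(priors, key=lambda p: (math.hypot(mid[1] - p[2][0],
                                                        mid[0] - p[2][1]), p[0]))
        per[nearest[0]].append(i)
    chains = {}
    lengths = {}
    for wid, idxs in per.items():
        parts = [segments[i] for i in idxs]
        chains[wid] = (np.concatenate(parts) if parts
                       else np.empty((0, 2), dtype=int))
        lengths[wid] = sum(chain_length(segments[i]) for i in idxs)
    resid = sum(abs(lengths[p[0]] - p[1]) for p in priors)
    return SegmentAssignment(
        worm_ids=[p[0] for p in priors], segments_per_worm=per,
        assembled_chains=chains, assembled_lengths=lengths,
        residual=float(resid), fallback=True,
    )


def _chain_centroid(segments, order) -> np.ndarray:
    pix = _assemble(segments, order)
    return pix.astype(float).mean(axis=0) if len(pix) else np.zeros(2)


def assign_segments(segments: list[np.ndarray],
                    priors: list[tuple[int, float, tuple[float, float]]],
                    cfg: SkeletonConfig | None = None) -> SegmentAssignment:
    """Distribute post-split skeleton segments among colliding worms.

    ``priors`` holds (worm_id, pre-collision skeleton length, last centre
    (x, y)) for each implicated worm.  For two worms the search is exact:
    every subset split is scored by the summed absolute length residual,
    subject to each worm's subset being chainable end-to-end through the
    removed branchpoint sites (junction gaps <= ``connect_tol``).  Ties are
    broken in favour of placing the smaller worm id nearer its recorded
    centre.  When no chainable split exists, segments fall back to a
    nearest-centroid split flagged on the result.
    """
    cfg = cfg or SkeletonConfig()
    if not segments:
        raise ValueError("no segments to assign")
    priors = sorted(priors, key=lambda p: p[0])
    if len(priors) != 2:
        return _fallback_centroid(segments, priors)

    if len(segments) == 1 and len(segments[0]) >= 4:
        split = _split_single_segment(segments[0], priors, cfg)
        # the chain could instead belong to one worm outright
        (id1, l1, _), (id2, l2, _) = priors
        total = chain_length(segments[0])
        solo_resids = {id1: abs(total - l1) + l2, id2: abs(total - l2) + l1}
        solo_id = min(solo_resids, key=lambda w: (solo_resids[w], w))
        if split.residual <= solo_resids[solo_id]:
            return split
        other = id2 if solo_id == id1 else id1
        return SegmentAssignment(
            worm_ids=[id1, id2],
            segments_per_worm={solo_id: [0], other: []},
            assembled_chains={solo_id: segments[0],
                              other: np.empty((0, 2), dtype=int)},
            assembled_lengths={solo_id: total, other: 0.0},
            residual=float(solo_resids[solo_id]),
        )

    n = len(segments)
    if n > 12:
        # keep the 12 longest segments in the exact search, park the rest
        lengths = [chain_length(s) for s in segments]
        keep = sorted(sorted(range(n), key=lambda i: -lengths[i])[:12])
        kept = [segments[i] for i in keep]
        sub = assign_segments(kept, priors, cfg)
        remap = {k: keep[k] for k in range(len(keep))}
        sub.segments_per_worm = {w: [remap[i] for i in idxs]
                                 for w, idxs in sub.segments_per_worm.items()}
        sub.shared_segments = [remap[i] for i in sub.shared_segments]
        return sub

    table = _chain_dp(segments, cfg.connect_tol)
    seg_len = [chain_length(s) for s in segments]
    (id1, l1, c1), (id2, l2, c2) = priors
    full = (1 << n) - 1

    def asm_len(mask) -> float:
        gap = table[mask][0]
        return gap + sum(seg_len[i] for i in range(n) if mask & (1 << i))

    def score(m1: int, m2: int):
        """(residual, #shared, tie distance, m1) for one candidate split."""
        r1 = abs(asm_len(m1) - l1)
        r2 = abs(asm_len(m2) - l2)
        cen = _chain_centroid(segments, table[m1][1]) if m1 else np.zeros(2)
        tie = math.hypot(cen[1] - c1[0], cen[0] - c1[1]) if m1 else math.inf
        return ((round(r1 + r2, 9), bin(m1 & m2).count("1"),
                 round(tie, 9), m1), r1, r2)

    # pass 1: exclusive splits (every segment to exactly one worm)
    best = None
    for m1 in table:
        m2 = full ^ m1
        if m2 in table:
            cand = score(m1, m2)
            if best is None or cand[0] < best[0]:
                best = cand + (m1, m2)
    # pass 2: allow segments shared by both worms when no exclusive split
    # exists or one leaves a worm's length residual above tolerance
    need_shared = (best is None
                   or best[1] > cfg.shared_tol * l1
                   or best[2] > cfg.shared_tol * l2)
    if need_shared:
        for m1 in table:
            need = full ^ m1
            sub = m1
            while True:  # all submasks of m1, including 0
                m2 = need | sub
                if m2 in table:
                    cand = score(m1, m2)
                    if best is None or cand[0] < best[0]:
                        best = cand + (m1, m2)
                if sub == 0:
                    break
                sub = (sub - 1) & m1
    if best is None:
        return _fallback_centroid(segments, priors)

    _, _, _, m1, m2 = best
    masks = {id1: m1, id2: m2}
    shared = [i for i in range(n) if (m1 & m2) & (1 << i)]
    per = {}
    chains = {}
    lengths = {}
    for wid in (id1, id2):
        order = table[masks[wid]][1]
        per[wid] = [i for i, _ in order]
        chains[wid] = _assemble(segments, order)
        lengths[wid] = asm_len(masks[wid])
    residual = abs(lengths[id1] - l1) + abs(lengths[id2] - l2)
    return SegmentAssignment(
        worm_ids=[id1, id2], segments_per_worm=per,
        assembled_chains=chains, assembled_lengths=lengths,
        shared_segments=shared, residual=float(residual),
    )
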
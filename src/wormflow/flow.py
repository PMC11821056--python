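"""Inter-trajectory stage: min-cost network flow over trajectory fragments.

Each trajectory fragment becomes a split vertex (u_i, v_i) with an internal
detection edge; the source feeds every u_i through an entry edge, every v_i
reaches the sink through an exit edge, and temporally compatible fragments
are joined by transition edges whose cost blends an appearance term (a
Bhattacharyya-style dissimilarity between grayscale profiles sampled at L
skeleton points) and a velocity term (cosine dissimilarity).  All capacities
are one, so an integral minimum-cost flow of k units decomposes into k
vertex-disjoint source-to-sink paths — the k worm trajectories.  The solver
sweeps k upward with successive shortest paths and stops at the flow value
that minimizes the total cost.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .config import CostConfig
from .skeleton import SkeletonPath

if TYPE_CHECKING:  # pragma: no cover
    from .intra import Tracklet

__all__ = [
    "FlowGraph", "TrajectorySet", "appearance_profile", "appearance_cost",
    "velocity_cost", "transition_cost", "build_graph", "solve",
]

_EPS_SPEED = 1e-6


def appearance_profile(frame: np.ndarray, skel: SkeletonPath,
                       mask_size: int = 5) -> np.ndarray:
    """Mean grayscale in an M x M window around each resampled skeleton point.

    Windows are clipped at the frame border; a point whose window holds no
    pixels at all is an error.
    """
    r = mask_size // 2
    H, W = frame.shape
    out = np.empty(len(skel.resampled))
    for k, (x, y) in enumerate(skel.resampled):
        ci, ri = int(round(x)), int(round(y))
        r0, r1 = max(ri - r, 0), min(ri + r + 1, H)
        c0, c1 = max(ci - r, 0), min(ci + r + 1, W)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"skeleton point ({x:.1f}, {y:.1f}) has an empty window")
        out[k] = float(frame[r0:r1, c0:c1].mean())
    return out


def appearance_cost(q: np.ndarray, c: np.ndarray,
                    sqrt_variant: bool = False) -> float:
    """Appearance dissimilarity of two grayscale profiles, in [0, 1].

    Profiles are normalized to unit sum and compared through the
    Bhattacharyya coefficient BC = sum_l sqrt(q_l * c_l); the cost is
    1 - BC (or sqrt(1 - BC) with ``sqrt_variant``).
    """
    q = np.asarray(q, dtype=float)
    c = np.asarray(c, dtype=float)
    if q.shape != c.shape:
        raise ValueError("profile lengths differ")
    if (q < 0).any() or (c < 0).any():
        raise ValueError("profiles must be non-negative")
    qs, cs = q.sum(), c.sum()
    if qs <= 0 or cs <= 0:
        raise ValueError("zero-sum appearance profile")
    bc = float(np.sqrt((q / qs) * (c / cs)).sum())
    d = min(max(1.0 - bc, 0.0), 1.0)
    return math.sqrt(d) if sqrt_variant else d


def velocity_cost(v1, v2) -> float:
    """Velocity dissimilarity from cosine similarity, mapped onto [0, 1].

    Parallel motion costs 0, antiparallel 1, orthogonal 0.5; a near-zero
    speed carries no direction information and returns the neutral 0.5.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = float(np.hypot(*v1)), float(np.hypot(*v2))
    if n1 < _EPS_SPEED or n2 < _EPS_SPEED:
        return 0.5
    cos = float(np.dot(v1, v2)) / (n1 * n2)
    cos = min(max(cos, -1.0), 1.0)
    return (1.0 - cos) / 2.0


def transition_cost(i: "Tracklet", j: "Tracklet", cfg: CostConfig) -> float:
    """Linking cost between two fragments: weighted appearance + velocity.

    Requires j to start strictly after i ends, within ``max_gap`` frames.
    """
    if not (j.t_start > i.t_end and j.t_start - i.t_end <= cfg.max_gap):
        raise ValueError("fragments are not temporally linkable")
    if i.appearance is None or j.appearance is None:
        ca = 0.5  # no appearance recorded: uninformative
    else:
        ca = appearance_cost(i.appearance, j.appearance, cfg.sqrt_bhattacharyya)
    cv = velocity_cost(i.velocity, j.velocity)
    return cfg.w_a * ca + cfg.w_v * cv


@dataclass
class FlowGraph:
    """Unit-capacity split-vertex DAG over trajectory fragments."""

    tracklets: list               # sorted by id
    entry_edges: list[tuple[int, float]]        # (idx, cost)
    exit_edges: list[tuple[int, float]]
    det_edges: list[tuple[int, float]]
    trans_edges: list[tuple[int, int, float]]   # (idx_i, idx_j, cost)

    @property
    def n(self) -> int:
        return len(self.tracklets)


@dataclass
class TrajectorySet:
    """Vertex-disjoint source-to-sink paths: the recovered trajectories."""

    trajectories: list[list[int]]   # lists of tracklet ids, time-ordered
    total_cost: float
    n_flow: int


def build_graph(tracklets: list, cfg: CostConfig,
                dist_thr: float = 20.0) -> FlowGraph:
    """Construct the flow network over trajectory fragments.

    Transition edges are created only for temporally compatible pairs whose
    constant-velocity predicted position lies within ``dist_thr`` px per
    frame of gap from the other fragment's start.
    """
    tracklets = sorted(tracklets, key=lambda tr: tr.id)
    entry = [(i, cfg.c_enter) for i in range(len(tracklets))]
    exits = [(i, cfg.c_exit) for i in range(len(tracklets))]
    dets = [(i, cfg.c_det) for i in range(len(tracklets))]
    trans: list[tuple[int, int, float]] = []
    for a, ti in enumerate(tracklets):
        for b, tj in enumerate(tracklets):
            gap = tj.t_start - ti.t_end
            if gap < 1 or gap > cfg.max_gap:
                continue
            px = ti.last_pos[0] + ti.velocity[0] * gap
            py = ti.last_pos[1] + ti.velocity[1] * gap
            if math.hypot(px - tj.first_pos[0],
                          py - tj.first_pos[1]) > dist_thr * gap:
                continue
            trans.append((a, b, transition_cost(ti, tj, cfg)))
    return FlowGraph(tracklets=tracklets, entry_edges=entry, exit_edges=exits,
                     det_edges=dets, trans_edges=trans)


# --------------------------------------------------------------------------
# successive-shortest-path solver


class _MCMF:
    """Unit-capacity min-cost flow with residual edges."""

    def __init__(self, n_nodes: int):
        self.n = n_nodes
        self.head: list[list[int]] = [[] for _ in range(n_nodes)]
        self.to: list[int] = []
        self.cap: list[int] = []
        self.cost: list[float] = []

    def add(self, u: int, v: int, cost: float) -> None:
        self.head[u].append(len(self.to))
        self.to.append(v); self.cap.append(1); self.cost.append(cost)
        self.head[v].append(len(self.to))
        self.to.append(u); self.cap.append(0); self.cost.append(-cost)


def solve(graph: FlowGraph) -> TrajectorySet:
    """Find the flow value and routing minimizing the total cost.

    Successive shortest augmenting paths with node potentials; the per-path
    cost increments are non-decreasing, so augmentation stops at the first
    non-negative increment — that flow value is the global cost minimum
    (possibly zero paths).  Cost ties between augmenting paths are broken
    toward the path through the smallest fragment ids.
    """
    n = graph.n
    S, T = 0, 1
    u_of = lambda i: 2 + 2 * i
    v_of = lambda i: 3 + 2 * i
    net = _MCMF(2 + 2 * n)
    for i, c in graph.entry_edges:
        net.add(S, u_of(i), c)
    for i, c in graph.det_edges:
        net.add(u_of(i), v_of(i), c)
    for i, c in graph.exit_edges:
        net.add(v_of(i), T, c)
    for i, j, c in graph.trans_edges:
        net.add(v_of(i), u_of(j), c)

    # initial potentials: one relaxation sweep in topological order (the
    # graph is a DAG before any augmentation)
    order = [S] + [x for i in sorted(range(n),
                                     key=lambda i: (graph.tracklets[i].t_start,
                                                    graph.tracklets[i].id))
                   for x in (u_of(i), v_of(i))] + [T]
    INF = float("inf")
    pot = [INF] * net.n
    pot[S] = 0.0
    for u in order:
        if pot[u] == INF:
            continue
        for e in net.head[u]:
            if net.cap[e] > 0 and pot[u] + net.cost[e] < pot[net.to[e]]:
                pot[net.to[e]] = pot[u] + net.cost[e]
    big = max((abs(c) for c in net.cost), default=1.0) * net.n
    pot = [p if p < INF else big for p in pot]

    total = 0.0
    k = 0
    while True:
        # Dijkstra on reduced costs; heap carries the path so that equal-cost
        # alternatives resolve to the lexicographically smallest node sequence
        dist = [INF] * net.n
        via_edge: list[int | None] = [None] * net.n
        settled = [False] * net.n
        heap: list[tuple[float, tuple[int, ...], int | None]] = [(0.0, (S,), None)]
        while heap:
            d, path, eid = heapq.heappop(heap)
            u = path[-1]
            if settled[u]:
                continue
            settled[u] = True
            dist[u] = d
            via_edge[u] = eid
            for e in net.head[u]:
                v = net.to[e]
                if net.cap[e] <= 0 or settled[v]:
                    continue
                w = net.cost[e] + pot[u] - pot[v]
                if w < 0:
                    w = 0.0 if w > -1e-6 else w  # float slack; true negatives abort
                    if w < 0:
                        raise RuntimeError("negative reduced cost: potentials broken")
                heapq.heappush(heap, (d + w, path + (v,), e))
        if dist[T] == INF:
            break
        path_cost = dist[T] + pot[T] - pot[S]
        if path_cost >= -1e-12:
            break
        # augment one unit along the recovered path
        node = T
        while node != S:
            e = via_edge[node]
            net.cap[e] -= 1
            net.cap[e ^ 1] += 1
            node = net.to[e ^ 1]
        total += path_cost
        k += 1
        pot = [pot[i] + (dist[i] if dist[i] < INF else dist[T]) for i in range(net.n)]
        if k >= n:
            break

    # decompose the integral flow into source-to-sink paths
    used = [False] * len(net.to)
    trajectories: list[list[int]] = []
    for e in net.head[S]:
        if e % 2 == 0 and net.cap[e] == 0 and not used[e]:  # saturated forward edge
            used[e] = True
            ids = []
            node = net.to[e]
            while node != T:
                if node >= 2 and node % 2 == 0:  # u-node
                    ids.append(graph.tracklets[(node - 2) // 2].id)
                nxt = None
                for e2 in net.head[node]:
                    if e2 % 2 == 0 and net.cap[e2] == 0 and not used[e2]:
                        nxt = e2
                        break
                used[nxt] = True
                node = net.to[nxt]
            trajectories.append(ids)
    trajectories.sort(key=lambda ids: ids[0] if ids else -1)
    return TrajectorySet(trajectories=trajectories, total_cost=total, n_flow=k)
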
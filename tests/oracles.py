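"""Independent reference implementations used as test oracles.

Everything here is deliberately brute force and shares no code with the
package internals: exhaustive path-cover enumeration for the flow solver,
permutation-based segment chaining for the skeleton split, and a from-scratch
CLEAR-MOT accumulator.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from wormflow.flow import FlowGraph
from wormflow.intra import Tracklet

# --------------------------------------------------------------------------
# flow: exhaustive vertex-disjoint path-cover enumeration


def path_cover_oracle(graph: FlowGraph) -> float:
    """Minimum total cost over all vertex-disjoint path covers.

    A cover picks a subset U of tracklets and a set of transition edges
    inside U forming a partial matching (each node at most one incoming and
    one outgoing edge).  Edges go forward in time, so any such matching is a
    set of simple paths.  Cost = entry cost at every path head + exit cost at
    every path tail + detection cost per used node + chosen edge costs.  The
    empty cover costs 0.
    """
    n = graph.n
    ent = dict(graph.entry_edges)
    exi = dict(graph.exit_edges)
    det = dict(graph.det_edges)
    best = 0.0
    for used in range(1 << n):
        members = [i for i in range(n) if used & (1 << i)]
        if not members:
            continue
        edges = [(i, j, c) for i, j, c in graph.trans_edges
                 if used & (1 << i) and used & (1 << j)]
        base = sum(det[i] for i in members)

        def recurse(k: int, out_used: int, in_used: int, edge_cost: float):
            nonlocal best
            if k == len(edges):
                total = edge_cost + base
                for i in members:
                    if not out_used & (1 << i):
                        total += exi[i]
                    if not in_used & (1 << i):
                        total += ent[i]
                best = min(best, total)
                return
            recurse(k + 1, out_used, in_used, edge_cost)  # skip edge k
            i, j, c = edges[k]
            if not out_used & (1 << i) and not in_used & (1 << j):
                recurse(k + 1, out_used | (1 << i), in_used | (1 << j),
                        edge_cost + c)

        recurse(0, 0, 0, 0.0)
    return best


def random_flow_graph(rng: np.random.Generator, n_max: int = 8) -> FlowGraph:
    """A random temporal DAG with random costs, shaped like real graphs."""
    n = int(rng.integers(1, n_max + 1))
    starts = np.sort(rng.integers(0, 4 * n, size=n))
    tracklets = []
    for k in range(n):
        t0 = int(starts[k])
        t1 = t0 + int(rng.integers(0, 3))
        tracklets.append(Tracklet(
            id=k, frames=list(range(t0, t1 + 1)),
            positions=[(0.0, 0.0)] * (t1 - t0 + 1),
            boxes=[(0, 0, 1, 1)] * (t1 - t0 + 1),
            appearance=None, velocity=(0.0, 0.0), t_start=t0, t_end=t1))
    entry = [(i, float(rng.uniform(0.05, 0.8))) for i in range(n)]
    exits = [(i, float(rng.uniform(0.05, 0.8))) for i in range(n)]
    dets = [(i, float(rng.uniform(-1.0, -0.05))) for i in range(n)]
    trans = []
    for a in range(n):
        for b in range(n):
            if tracklets[b].t_start > tracklets[a].t_end and rng.random() < 0.5:
                trans.append((a, b, float(rng.uniform(0.0, 1.0))))
    return FlowGraph(tracklets=tracklets, entry_edges=entry, exit_edges=exits,
                     det_edges=dets, trans_edges=trans)


# --------------------------------------------------------------------------
# skeleton: brute-force segment chaining and split selection


def brute_chain_table(segments, connect_tol: float):
    """table[mask] = (min summed junction gap, order) by trying every
    permutation and flip pattern of the subset; infeasible masks absent."""
    n = len(segments)
    table = {0: (0.0, [])}
    for mask in range(1, 1 << n):
        idxs = [i for i in range(n) if mask & (1 << i)]
        best = None
        for perm in itertools.permutations(idxs):
            for flips in itertools.product((False, True), repeat=len(idxs)):
                gap = 0.0
                ok = True
                for (i, fi), (j, fj) in zip(zip(perm, flips),
                                            zip(perm[1:], flips[1:])):
                    tail = segments[i][0] if fi else segments[i][-1]
                    head = segments[j][-1] if fj else segments[j][0]
                    g = math.hypot(float(tail[0]) - float(head[0]),
                                   float(tail[1]) - float(head[1]))
                    if g > connect_tol:
                        ok = False
                        break
                    gap += g
                if ok and (best is None or gap < best[0] - 1e-12):
                    best = (gap, list(zip(perm, flips)))
        if best is not None:
            table[mask] = best
    return table


def oracle_assign(segments, priors, cfg):
    """Exhaustive re-implementation of the two-pass split selection.

    Returns (mask_worm1, mask_worm2, residual) for the sorted priors, using
    the same scoring and tie-break rule as the package but with the
    permutation-based chaining table above.
    """
    priors = sorted(priors, key=lambda p: p[0])
    (id1, l1, c1), (id2, l2, c2) = priors
    n = len(segments)
    seg_len = [_seg_length(s) for s in segments]
    table = brute_chain_table(segments, cfg.connect_tol)
    full = (1 << n) - 1

    def asm_len(mask):
        return table[mask][0] + sum(seg_len[i] for i in range(n)
                                    if mask & (1 << i))

    def score(m1, m2):
        r1 = abs(asm_len(m1) - l1)
        r2 = abs(asm_len(m2) - l2)
        if m1:
            pix = np.concatenate([segments[i][::-1] if f else segments[i]
                                  for i, f in table[m1][1]]).astype(float)
            cen = pix.mean(axis=0)
            tie = math.hypot(cen[1] - c1[0], cen[0] - c1[1])
        else:
            tie = math.inf
        return ((round(r1 + r2, 9), bin(m1 & m2).count("1"),
                 round(tie, 9), m1), r1, r2)

    best = None
    for m1 in table:
        m2 = full ^ m1
        if m2 in table:
            cand = score(m1, m2)
            if best is None or cand[0] < best[0]:
                best = cand + (m1, m2)
    need_shared = (best is None or best[1] > cfg.shared_tol * l1
                   or best[2] > cfg.shared_tol * l2)
    if need_shared:
        for m1 in table:
            need = full ^ m1
            sub = m1
            while True:
                m2 = need | sub
                if m2 in table:
                    cand = score(m1, m2)
                    if best is None or cand[0] < best[0]:
                        best = cand + (m1, m2)
                if sub == 0:
                    break
                sub = (sub - 1) & m1
    if best is None:
        return None
    key, _r1, _r2, m1, m2 = best
    return m1, m2, float(key[0])


def _seg_length(seg) -> float:
    seg = np.asarray(seg, dtype=float)
    if len(seg) < 2:
        return 0.0
    d = np.diff(seg, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


# --------------------------------------------------------------------------
# evaluation: independent CLEAR-MOT accumulator


def _iou(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


class RefClearMot:
    """Brute-force CLEAR-MOT: carry-over kept, remainder matched by
    enumerating every partial injective gt->pred mapping and maximizing
    sum(1 + IoU) over above-threshold pairs."""

    def __init__(self, iou_thr: float = 0.3):
        self.thr = iou_thr
        self.fn = self.fp = self.idsw = self.gt = 0
        self.ious: list[float] = []
        self.last_hyp: dict[int, int] = {}
        self.prev: dict[int, int] = {}

    def update(self, gt_ids, gt_boxes, pred_ids, pred_boxes):
        fixed = {}  # gt idx -> pred idx
        for gi, gid in enumerate(gt_ids):
            pid = self.prev.get(gid)
            if pid in pred_ids:
                pi = pred_ids.index(pid)
                if pi not in fixed.values() and \
                        _iou(gt_boxes[gi], pred_boxes[pi]) >= self.thr:
                    fixed[gi] = pi
        g_free = [i for i in range(len(gt_ids)) if i not in fixed]
        p_free = [j for j in range(len(pred_ids)) if j not in fixed.values()]
        best = (-1.0, [])
        for r in range(min(len(g_free), len(p_free)) + 1):
            for gs in itertools.combinations(g_free, r):
                for ps in itertools.permutations(p_free, r):
                    vals = [_iou(gt_boxes[g], pred_boxes[p])
                            for g, p in zip(gs, ps)]
                    if any(v < self.thr for v in vals):
                        continue
                    gain = sum(1.0 + v for v in vals)
                    if gain > best[0]:
                        best = (gain, list(zip(gs, ps)))
        matches = sorted(list(fixed.items()) + best[1])
        pairs = {}
        for gi, pi in matches:
            gid, pid = gt_ids[gi], pred_ids[pi]
            self.ious.append(_iou(gt_boxes[gi], pred_boxes[pi]))
            if gid in self.last_hyp and self.last_hyp[gid] != pid:
                self.idsw += 1
            self.last_hyp[gid] = pid
            pairs[gid] = pid
        self.fn += len(gt_ids) - len(matches)
        self.fp += len(pred_ids) - len(matches)
        self.gt += len(gt_ids)
        self.prev = pairs

    def mota(self) -> float:
        return 1.0 - (self.fn + self.fp + self.idsw) / self.gt

    def motp(self) -> float:
        return sum(self.ious) / len(self.ious)


def random_event_stream(rng: np.random.Generator):
    """Random (gt_ids, gt_boxes, pred_ids, pred_boxes) per frame, with
    drops, clutter, jitter, and occasional identity swaps."""
    n_obj = int(rng.integers(2, 5))
    n_frames = int(rng.integers(6, 12))
    centres = rng.uniform(20, 180, size=(n_obj, 2))
    ids = list(range(1, n_obj + 1))
    pred_of = {g: g + 100 for g in ids}
    frames = []
    for _ in range(n_frames):
        centres = centres + rng.uniform(-4, 4, size=centres.shape)
        gt_ids, gt_boxes, pred_ids, pred_boxes = [], [], [], []
        if rng.random() < 0.25:  # swap two prediction identities
            a, b = rng.choice(ids, size=2, replace=False)
            pred_of[a], pred_of[b] = pred_of[b], pred_of[a]
        for k, g in enumerate(ids):
            x, y = centres[k]
            gt_ids.append(g)
            gt_boxes.append((float(x), float(y), 12.0, 12.0))
            if rng.random() < 0.15:  # missed detection
                continue
            jx, jy = rng.uniform(-3, 3, size=2)
            pred_ids.append(pred_of[g])
            pred_boxes.append((float(x + jx), float(y + jy),
                               float(12 + rng.uniform(-2, 2)),
                               float(12 + rng.uniform(-2, 2))))
        if rng.random() < 0.2:  # clutter false alarm
            x, y = rng.uniform(20, 180, size=2)
            pred_ids.append(999)
            pred_boxes.append((float(x), float(y), 12.0, 12.0))
        frames.append((gt_ids, gt_boxes, pred_ids, pred_boxes))
    return frames
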
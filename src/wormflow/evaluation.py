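"""CLEAR-MOT scoring of tracker output against ground truth.

Per frame, ground-truth and predicted boxes are matched by IoU: matches
carried over from the previous frame are kept while they still overlap
above threshold, and the remainder are matched by optimal assignment
maximizing IoU.  Unmatched ground truth counts as a miss (FN), unmatched
predictions as false alarms (FP), and a ground-truth track whose matched
hypothesis id differs from its most recent one counts an identity switch
(IDSW).  MOTA = 1 - (FN + FP + IDSW) / GT; MOTP is the mean IoU over all
matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import EvalConfig

__all__ = [
    "MOTMetrics", "MOTAccumulator", "iou", "match_frame", "mota", "motp",
    "evaluate_tracks", "evaluate_files",
]

Box = tuple[float, float, float, float]  # (left, top, w, h)


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric has an empty denominator."""


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two (left, top, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def mota(fn: int, fp: int, idsw: int, gt: int) -> float:
    """Multiple-object tracking accuracy (may be negative)."""
    if gt <= 0:
        raise UndefinedMetricError("MOTA undefined with zero ground-truth detections")
    return 1.0 - (fn + fp + idsw) / gt


def motp(matched_ious: list[float]) -> float:
    """Multiple-object tracking precision: mean IoU over all matches."""
    if not matched_ious:
        raise UndefinedMetricError("MOTP undefined without any match")
    return float(np.mean(matched_ious))


@dataclass
class MOTMetrics:
    fn: int
    fp: int
    idsw: int
    gt: int
    matched_ious: list[float] = field(default_factory=list, repr=False)

    @property
    def mota(self) -> float:
        return mota(self.fn, self.fp, self.idsw, self.gt)

    @property
    def motp(self) -> float:
        return motp(self.matched_ious)

    def as_dict(self) -> dict:
        # MOTP is undefined with zero matches; report null rather than fail
        # so an all-miss evaluation still yields its MOTA
        return {"FN": self.fn, "FP": self.fp, "IDSW": self.idsw, "GT": self.gt,
                "MOTA": self.mota,
                "MOTP": self.motp if self.matched_ious else None}


def match_frame(gt_boxes: list[Box], pred_boxes: list[Box], iou_thr: float,
                prefer: dict[int, int] | None = None
                ) -> list[tuple[int, int, float]]:
    """Match one frame's boxes by IoU at threshold ``iou_thr``.

    ``prefer`` maps gt index -> pred index pairs to keep if they still
    overlap above threshold (the CLEAR-MOT carry-over rule); the rest is an
    optimal assignment maximizing total IoU.  Returns (gt_idx, pred_idx,
    iou) triples.
    """
    matches: list[tuple[int, int, float]] = []
    g_free = set(range(len(gt_boxes)))
    p_free = set(range(len(pred_boxes)))
    for gi, pi in (prefer or {}).items():
        if gi in g_free and pi in p_free:
            v = iou(gt_boxes[gi], pred_boxes[pi])
            if v >= iou_thr:
                matches.append((gi, pi, v))
                g_free.discard(gi)
                p_free.discard(pi)
    gl, pl = sorted(g_free), sorted(p_free)
    if gl and pl:
        cost = np.ones((len(gl), len(pl)))
        for i, gi in enumerate(gl):
            for j, pi in enumerate(pl):
                v = iou(gt_boxes[gi], pred_boxes[pi])
                if v >= iou_thr:
                    cost[i, j] = -v
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < 0:
                matches.append((gl[i], pl[j], -cost[i, j]))
    return sorted(matches)


class MOTAccumulator:
    """Streams frames and accumulates CLEAR-MOT event counts."""

    def __init__(self, iou_thr: float = 0.3):
        self.iou_thr = iou_thr
        self.fn = 0
        self.fp = 0
        self.idsw = 0
        self.gt = 0
        self.matched_ious: list[float] = []
        self._last_hyp: dict[int, int] = {}    # gt id -> most recent matched pred id
        self._prev_pairs: dict[int, int] = {}  # gt id -> pred id matched last frame

    def update(self, gt_ids: list[int], gt_boxes: list[Box],
               pred_ids: list[int], pred_boxes: list[Box]) -> None:
        prefer = {}
        for gi, gid in enumerate(gt_ids):
            pid = self._prev_pairs.get(gid)
            if pid is not None and pid in pred_ids:
                prefer[gi] = pred_ids.index(pid)
        matches = match_frame(gt_boxes, pred_boxes, self.iou_thr, prefer)
        matched_g = set()
        matched_p = set()
        pairs: dict[int, int] = {}
        for gi, pi, v in matches:
            gid, pid = gt_ids[gi], pred_ids[pi]
            matched_g.add(gi)
            matched_p.add(pi)
            self.matched_ious.append(v)
            if gid in self._last_hyp and self._last_hyp[gid] != pid:
                self.idsw += 1
            self._last_hyp[gid] = pid
            pairs[gid] = pid
        self.fn += len(gt_ids) - len(matched_g)
        self.fp += len(pred_ids) - len(matched_p)
        self.gt += len(gt_ids)
        self._prev_pairs = pairs

    def metrics(self) -> MOTMetrics:
        return MOTMetrics(fn=self.fn, fp=self.fp, idsw=self.idsw, gt=self.gt,
                          matched_ious=self.matched_ious)


def evaluate_tracks(gt_rows: list[tuple[int, int, Box]],
                    pred_rows: list[tuple[int, int, Box]],
                    cfg: EvalConfig | None = None) -> MOTMetrics:
    """Score prediction rows against ground-truth rows.

    Rows are (frame, id, (left, top, w, h)) with any consistent coordinate
    origin.  Frames present in either stream are scored; a frame with no
    predictions contributes misses only.
    """
    cfg = cfg or EvalConfig()
    by_frame_gt: dict[int, list[tuple[int, Box]]] = {}
    by_frame_pr: dict[int, list[tuple[int, Box]]] = {}
    for f, oid, box in gt_rows:
        by_frame_gt.setdefault(f, []).append((oid, box))
    for f, oid, box in pred_rows:
        by_frame_pr.setdefault(f, []).append((oid, box))
    acc = MOTAccumulator(cfg.iou_thr)
    for f in sorted(set(by_frame_gt) | set(by_frame_pr)):
        g = by_frame_gt.get(f, [])
        p = by_frame_pr.get(f, [])
        acc.update([x[0] for x in g], [x[1] for x in g],
                   [x[0] for x in p], [x[1] for x in p])
    return acc.metrics()


def evaluate_files(gt_csv: str | Path, pred_csv: str | Path,
                   cfg: EvalConfig | None = None) -> MOTMetrics:
    """Score two MOTChallenge-style CSV files."""
    from .synthetic import read_gt
    return evaluate_tracks(read_gt(gt_csv), read_gt(pred_csv), cfg)


def write_metrics(metrics: MOTMetrics, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics.as_dict(), fh, indent=2)
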
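"""End-to-end tracking: frames -> detections -> fragments -> trajectories."""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import PipelineConfig
from .flow import TrajectorySet, build_graph, solve
from .intra import Tracklet, run_intra

__all__ = ["track_video", "trajectory_rows", "write_tracks", "load_frames"]

log = logging.getLogger("wormflow")


def load_frames(path: str | Path) -> list[np.ndarray]:
    """Read an image-sequence directory (PNG/TIFF) or a multi-page TIFF."""
    p = Path(path)
    if p.is_dir():
        files = sorted(list(p.glob("*.png")) + list(p.glob("*.tif"))
                       + list(p.glob("*.tiff")))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {p}")
        frames = []
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:
                raise OSError(f"unreadable frame: {f}") from exc
            if img.ndim == 3:
                img = img[..., 0]
            frames.append(np.asarray(img, dtype=np.uint8))
        return frames
    stack = iio.imread(p)
    if stack.ndim == 2:
        stack = stack[None]
    return [np.asarray(fr, dtype=np.uint8) for fr in stack]


def track_video(frames: list[np.ndarray], cfg: PipelineConfig
                ) -> tuple[TrajectorySet, list[Tracklet]]:
    """Run the full two-stage tracker on a frame sequence."""
    tracklets = run_intra(frames, cfg)
    log.info("intra stage: %d trajectory fragments", len(tracklets))
    graph = build_graph(tracklets, cfg.flow, dist_thr=cfg.intra.dist_thr)
    log.info("flow graph: %d vertices, %d transition edges",
             graph.n, len(graph.trans_edges))
    trajset = solve(graph)
    log.info("flow solution: %d trajectories, total cost %.3f",
             trajset.n_flow, trajset.total_cost)
    return trajset, tracklets


def trajectory_rows(trajset: TrajectorySet, tracklets: list[Tracklet],
                    interpolate_gaps: bool = True
                    ) -> list[tuple[int, int, tuple[float, float, float, float]]]:
    """Flatten trajectories into (frame, traj_id, box) rows (0-based frames).

    Frames skipped between consecutive fragments of one trajectory are
    optionally filled by linear box interpolation.
    """
    by_id = {tr.id: tr for tr in tracklets}
    rows: list[tuple[int, int, tuple[float, float, float, float]]] = []
    for k, ids in enumerate(trajset.trajectories, start=1):
        seq: list[tuple[int, tuple[float, float, float, float]]] = []
        for tid in ids:
            tr = by_id[tid]
            for f, box in zip(tr.frames, tr.boxes):
                seq.append((f, tuple(float(v) for v in box)))
        seq.sort()
        filled = []
        for idx, (f, box) in enumerate(seq):
            if interpolate_gaps and idx > 0:
                f0, b0 = seq[idx - 1]
                for g in range(f0 + 1, f):
                    w = (g - f0) / (f - f0)
                    filled.append((g, tuple((1 - w) * a + w * b
                                            for a, b in zip(b0, box))))
            filled.append((f, box))
        rows.extend((f, k, box) for f, box in filled)
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows


def write_tracks(rows, path: str | Path) -> None:
    """Write trajectory rows as a MOTChallenge CSV (1-based frames/pixels)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for f, tid, (left, top, w, h) in rows:
            cx, cy = left + w / 2, top + h / 2
            writer.writerow([f + 1, tid, round(left + 1, 2), round(top + 1, 2),
                             round(w, 2), round(h, 2), 1,
                             round(cx + 1, 2), round(cy + 1, 2), -1])


def write_sidecar(trajset: TrajectorySet, path: str | Path) -> None:
    """JSON sidecar: trajectory composition and the solution cost."""
    with open(path, "w") as fh:
        json.dump({
            "n_trajectories": trajset.n_flow,
            "total_cost": trajset.total_cost,
            "tracklets_per_trajectory": trajset.trajectories,
        }, fh, indent=2)
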
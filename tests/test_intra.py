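"""Intra-trajectory stage: gating, frame linking, windowing, collisions."""

import itertools
import math

import numpy as np
import pytest

from wormflow.config import (DetectionConfig, MatchParams, PipelineConfig,
                             SkeletonConfig, SimConfig)
from wormflow.detection import detect_frame
from wormflow.intra import (WormDetection, build_tracklets, link_frame,
                            match_pair, run_intra, track_collision, _Chain)
from wormflow.skeleton import (SkeletonPath, longest_path_chain,
                               skeletonize_blob, chain_length)
from wormflow.synthetic import simulate

from conftest import worm_frame


def stub_path(x: float, y: float, orient: float = 0.0) -> SkeletonPath:
    pix = np.array([[int(y), int(x) - 1], [int(y), int(x) + 1]])
    return SkeletonPath(ordered_pixels=pix, length=2.0, centre=(x, y),
                        orientation=orient % math.pi,
                        resampled=np.tile([x, y], (10, 1)).astype(float))


def det(frame: int, x: float, y: float, orient: float = 0.0) -> WormDetection:
    return WormDetection(frame=frame, path=stub_path(x, y, orient),
                         bbox=(int(x) - 5, int(y) - 5, 10, 10))


# --------------------------------------------------------------------------
# match_pair


def test_match_pair_identity():
    p = stub_path(10, 10, 0.3)
    assert match_pair(p, p, MatchParams())


def test_match_pair_small_displacement():
    assert match_pair(stub_path(10, 10), stub_path(11, 10), MatchParams())


def test_match_pair_boundary_inclusive():
    params = MatchParams(dist_thr=20.0, angle_thr=math.pi / 4)
    a = stub_path(0, 0, 0.0)
    b = stub_path(20.0, 0.0, math.pi / 4)  # d = thr exactly, dO = thr exactly
    assert match_pair(a, b, params)
    just_over = stub_path(20.0 + 1e-6, 0.0, math.pi / 4 + 1e-6)
    assert not match_pair(a, just_over, params)


def test_match_pair_angle_folding():
    # orientations 0.1 and pi - 0.1 differ by 0.2 once folded
    a = stub_path(0, 0, 0.1)
    b = stub_path(1, 0, math.pi - 0.1)
    assert match_pair(a, b, MatchParams(angle_thr=0.25))
    assert not match_pair(a, b, MatchParams(angle_thr=0.15))


# --------------------------------------------------------------------------
# link_frame


def test_link_one_to_one():
    assert link_frame([det(0, 10, 10)], [det(1, 12, 10)],
                      MatchParams()) == [(0, 0)]


def test_link_no_gate_partner_unmatched():
    assert link_frame([det(0, 10, 10)], [det(1, 200, 200)],
                      MatchParams()) == []


def _brute_force_link(dets_t, dets_t1, params):
    best = None
    idx1 = range(len(dets_t1))
    for r in range(min(len(dets_t), len(dets_t1)), -1, -1):
        for subset in itertools.combinations(range(len(dets_t)), r):
            for perm in itertools.permutations(idx1, r):
                if not all(match_pair(dets_t[i].path, dets_t1[j].path, params)
                           for i, j in zip(subset, perm)):
                    continue
                cost = sum(math.hypot(
                    dets_t1[j].centre[0] - dets_t[i].centre[0],
                    dets_t1[j].centre[1] - dets_t[i].centre[1])
                    for i, j in zip(subset, perm))
                # maximize matches first, then minimize distance
                key = (-r, cost)
                if best is None or key < best[0]:
                    best = (key, sorted(zip(subset, perm)))
    return best[1] if best else []


def test_link_crossed_distances_respect_angle_gate():
    dets_t = [det(0, 0, 0, 0.05), det(0, 12, 0, 1.20)]
    dets_t1 = [det(1, 8, 0, 0.05), det(1, 4, 0, 1.25)]
    params = MatchParams(dist_thr=20, angle_thr=math.pi / 4)
    got = link_frame(dets_t, dets_t1, params)
    assert got == [(0, 0), (1, 1)]  # crossing is cheaper but gate forbids it
    assert got == _brute_force_link(dets_t, dets_t1, params)


def test_link_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    params = MatchParams(dist_thr=15, angle_thr=0.6)
    for _ in range(30):
        n, m = rng.integers(1, 4, size=2)
        dets_t = [det(0, *rng.uniform(0, 40, 2), rng.uniform(0, math.pi))
                  for _ in range(n)]
        dets_t1 = [det(1, *rng.uniform(0, 40, 2), rng.uniform(0, math.pi))
                   for _ in range(m)]
        got = link_frame(dets_t, dets_t1, params)
        want = _brute_force_link(dets_t, dets_t1, params)
        assert len(got) == len(want)
        got_cost = sum(math.hypot(dets_t1[j].centre[0] - dets_t[i].centre[0],
                                  dets_t1[j].centre[1] - dets_t[i].centre[1])
                       for i, j in got)
        want_cost = sum(math.hypot(dets_t1[j].centre[0] - dets_t[i].centre[0],
                                   dets_t1[j].centre[1] - dets_t[i].centre[1])
                        for i, j in want)
        assert got_cost == pytest.approx(want_cost, abs=1e-9)


# --------------------------------------------------------------------------
# build_tracklets


def _walk(n_frames: int, step: float = 5.0):
    return [[det(t, 10 + step * t, 50)] for t in range(n_frames)]


def test_windowing_nine_frames_three_tracklets():
    tracklets = build_tracklets(_walk(9), MatchParams(window=3))
    assert len(tracklets) == 3
    assert [tr.frames for tr in tracklets] == [[0, 1, 2], [3, 4, 5], [6, 7, 8]]


def test_break_rule_short_tracklet():
    tracklets = build_tracklets(_walk(2), MatchParams(window=3))
    assert len(tracklets) == 1
    assert tracklets[0].frames == [0, 1]


def test_tracklet_velocity_and_span():
    (tr,) = build_tracklets(_walk(3), MatchParams(window=3))
    assert tr.velocity == pytest.approx((5.0, 0.0))
    assert (tr.t_start, tr.t_end) == (0, 2)
    assert tr.first_pos == (10.0, 50.0)
    assert tr.last_pos == (20.0, 50.0)


def test_two_separated_worms_six_frames():
    all_dets = [[det(t, 10 + 5 * t, 20), det(t, 10 + 5 * t, 150)]
                for t in range(6)]
    tracklets = build_tracklets(all_dets, MatchParams(window=3))
    assert len(tracklets) == 4
    ys = sorted({pos[1] for tr in tracklets for pos in tr.positions})
    assert ys == [20.0, 150.0]
    for tr in tracklets:
        assert len({pos[1] for pos in tr.positions}) == 1  # no mixing


def test_conservation_every_detection_once(small_video):
    cfg = PipelineConfig()
    tracklets, all_dets = run_intra(small_video.frames, cfg,
                                    collect_detections=True)
    n_dets = sum(len(d) for d in all_dets)
    assert sum(len(tr.frames) for tr in tracklets) == n_dets
    for tr in tracklets:
        assert tr.frames == list(range(tr.t_start, tr.t_end + 1))
        for (x0, y0), (x1, y1) in zip(tr.positions, tr.positions[1:]):
            assert math.hypot(x1 - x0, y1 - y0) <= cfg.intra.dist_thr + 1e-9


# --------------------------------------------------------------------------
# track_collision


def _chain(cid: int, centres, length: float) -> _Chain:
    x, y = centres[-1]
    last = det(0, x, y)
    last.path.length = length
    c = _Chain(id=cid, last_det=last, last_frame=0, buffer=[])
    c.centres = list(centres)
    return c


def _crossing_blob(frame):
    blobs = detect_frame(frame, 1, DetectionConfig())
    assert len(blobs) == 1 and blobs[0].is_collided
    return blobs[0]


@pytest.fixture(scope="module")
def collision_setup(crossing_frame):
    frame, (a, b) = crossing_frame
    solo_len = {}
    for s in (a, b):
        blob = detect_frame(worm_frame([s]), 0, DetectionConfig())[0]
        solo_len[s.id] = chain_length(longest_path_chain(skeletonize_blob(blob)))
    return _crossing_blob(frame), frame.shape, solo_len


def test_collision_two_implicated_two_detections(collision_setup):
    blob, shape, solo_len = collision_setup
    chains = [_chain(1, [(80, 82), (85, 87)], solo_len[1]),
              _chain(2, [(120, 82), (115, 87)], solo_len[2])]
    dets = track_collision(blob, chains, SkeletonConfig(), MatchParams(), shape)
    assert len(dets) == 2
    assert all(d.from_collision for d in dets)
    assert {d.bound_chain_id for d in dets} == {1, 2}
    (x1, y1), (x2, y2) = dets[0].centre, dets[1].centre
    assert math.hypot(x1 - x2, y1 - y2) > 1.0


def test_collision_one_implicated_single_worm(collision_setup):
    blob, shape, solo_len = collision_setup
    chains = [_chain(1, [(80, 82), (85, 87)], solo_len[1]),
              _chain(2, [(400, 400), (400, 400)], solo_len[2])]
    dets = track_collision(blob, chains, SkeletonConfig(), MatchParams(), shape)
    assert len(dets) == 1
    assert not dets[0].from_collision


def test_collision_three_implicated_best_two(collision_setup):
    blob, shape, solo_len = collision_setup
    chains = [_chain(1, [(80, 82), (85, 87)], solo_len[1]),
              _chain(2, [(120, 82), (115, 87)], solo_len[2]),
              _chain(3, [(140, 130), (138, 128)], 80.0)]
    dets = track_collision(blob, chains, SkeletonConfig(), MatchParams(), shape)
    assert len(dets) == 2
    assert {d.bound_chain_id for d in dets} <= {1, 2, 3}


def test_collision_freezes_prior_at_onset(collision_setup):
    blob, shape, solo_len = collision_setup
    c1 = _chain(1, [(80, 82), (85, 87)], solo_len[1])
    c2 = _chain(2, [(120, 82), (115, 87)], solo_len[2])
    track_collision(blob, [c1, c2], SkeletonConfig(), MatchParams(), shape)
    assert c1.in_collision and c2.in_collision
    assert c1.prior_length == pytest.approx(solo_len[1])
    # a second collision frame must not overwrite the recorded prior
    c1.last_det.path.length = 5.0
    track_collision(blob, [c1, c2], SkeletonConfig(), MatchParams(), shape)
    assert c1.prior_length == pytest.approx(solo_len[1])


def test_collision_free_video_reconstructs_paths():
    video = simulate(SimConfig(n_worms=2, n_frames=12, frame_size=(300, 300),
                               collision_rate=0.0, seed=4))
    cfg = PipelineConfig()
    tracklets = run_intra(video.frames, cfg)
    assert all(not tr.from_collision for tr in tracklets)
    # every tracklet's positions stay close to exactly one gt worm
    gt = video.gt_by_frame()
    for tr in tracklets:
        owners = set()
        for f, (x, y) in zip(tr.frames, tr.positions):
            owner = min(gt[f], key=lambda r: math.hypot(x - r.centroid[0],
                                                        y - r.centroid[1]))
            owners.add(owner.id)
        assert len(owners) == 1
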
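"""Skeletonization, branchpoint splitting, and segment assignment."""

import math

import numpy as np
import pytest

from wormflow.config import DetectionConfig, SkeletonConfig
from wormflow.detection import detect_frame
from wormflow.skeleton import (DegenerateSkeletonError, SkeletonGraph,
                               assign_segments, chain_length,
                               longest_path_chain, path_descriptor,
                               skeletonize_blob, split_at_branchpoints)

from conftest import straight_worm, worm_frame

_NBHD = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def graph_from_points(points) -> SkeletonGraph:
    """Build a SkeletonGraph from explicit pixel coordinates."""
    pts = set(points)
    adjacency = {p: [q for dr, dc in _NBHD
                     if (q := (p[0] + dr, p[1] + dc)) in pts] for p in pts}
    branch = {p for p, nb in adjacency.items() if len(nb) >= 3}
    ends = {p for p, nb in adjacency.items() if len(nb) == 1}
    return SkeletonGraph(points=pts, adjacency=adjacency,
                         branchpoints=branch, endpoints=ends)


def single_blob(frame):
    blobs = detect_frame(frame, 0, DetectionConfig())
    assert len(blobs) == 1
    return blobs[0]


# --------------------------------------------------------------------------
# skeletonize_blob


def test_single_worm_skeleton_simple_path():
    blob = single_blob(worm_frame([straight_worm(100, 100)]))
    skel = skeletonize_blob(blob)
    assert len(skel.branchpoints) == 0
    assert len(skel.endpoints) == 2


def test_crossing_worms_have_branchpoint(crossing_frame):
    frame, _ = crossing_frame
    skel = skeletonize_blob(single_blob(frame))
    assert len(skel.branchpoints) >= 1


def test_skeleton_in_global_coordinates():
    blob = single_blob(worm_frame([straight_worm(120, 80)]))
    skel = skeletonize_blob(blob)
    rows = [p[0] for p in skel.points]
    cols = [p[1] for p in skel.points]
    left, top, w, h = blob.bbox
    assert top <= min(rows) and max(rows) < top + h
    assert left <= min(cols) and max(cols) < left + w


def test_tiny_blob_degenerate():
    from wormflow.detection import Blob
    blob = Blob(frame=0, coords=np.array([[0, 0], [0, 1]]), area=2,
                centroid=(0.5, 0.0), bbox=(0, 0, 2, 1), is_collided=False)
    with pytest.raises(DegenerateSkeletonError):
        skeletonize_blob(blob)


def test_disc_skeleton_degenerates():
    frame = np.full((100, 100), 200, dtype=np.uint8)
    yy, xx = np.mgrid[:100, :100]
    frame[(yy - 50) ** 2 + (xx - 50) ** 2 <= 10 ** 2] = 60
    skel = skeletonize_blob(single_blob(frame))
    chain = longest_path_chain(skel)
    assert chain_length(chain) < 15  # no worm-scale path in a disc


# --------------------------------------------------------------------------
# split_at_branchpoints


def _pixel_x():
    """Two diagonal chains crossing at (26, 26); arm lengths 2x28.28, 2x18.38."""
    main = [(i, i) for i in range(5, 48)]
    anti = [(i, 52 - i) for i in range(12, 41)]
    return main, anti


def test_split_x_crossing_four_segments():
    main, anti = _pixel_x()
    skel = graph_from_points(main + anti)
    assert skel.branchpoints == {(26, 26)}
    segments = split_at_branchpoints(skel)
    assert len(segments) == 4


def test_split_branchpoint_free_identity():
    chain = [(10, c) for c in range(10, 40)]
    skel = graph_from_points(chain)
    segments = split_at_branchpoints(skel)
    assert len(segments) == 1
    assert {tuple(p) for p in segments[0]} == set(chain)


def test_split_two_branchpoints_segment_count():
    # end-to-side contact: a straight chain with a stub branching off mid-way
    spine = [(20, c) for c in range(0, 41)]
    stub = [(20 - k, 20) for k in range(1, 15)]
    skel = graph_from_points(spine + stub)
    segments = split_at_branchpoints(skel)
    removal = set(skel.branchpoints)
    for p, nb in skel.adjacency.items():
        if sum(q in skel.branchpoints for q in nb) >= 2:
            removal.add(p)
    expect = graph_from_points(set(skel.points) - removal)
    assert len(segments) == len(
        {tuple(sorted(c)) for c in _components(expect)})


def _components(skel: SkeletonGraph):
    unvisited = set(skel.points)
    comps = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            p = stack.pop()
            for q in skel.adjacency[p]:
                if q in unvisited:
                    unvisited.discard(q)
                    comp.add(q)
                    stack.append(q)
        if len(comp) >= 3:
            comps.append(comp)
    return comps


def test_split_segments_disjoint_subset_of_skeleton(crossing_frame):
    frame, _ = crossing_frame
    skel = skeletonize_blob(single_blob(frame))
    segments = split_at_branchpoints(skel)
    seen = set()
    for seg in segments:
        pix = {tuple(p) for p in seg}
        assert pix <= skel.points
        assert not (pix & seen)
        seen |= pix


def test_min_segment_px_drops_short_stubs():
    spine = [(20, c) for c in range(0, 41)]
    stub = [(19, 20), (18, 21)]  # 2-px spur
    skel = graph_from_points(spine + stub)
    segments = split_at_branchpoints(skel, min_segment_px=3)
    assert all(len(s) >= 3 for s in segments)


# --------------------------------------------------------------------------
# path_descriptor


def test_descriptor_horizontal_chain():
    chain = np.array([(5, c) for c in range(10, 21)])
    d = path_descriptor(chain, L=10)
    assert d.orientation == pytest.approx(0.0)
    assert d.length == pytest.approx(10.0)
    assert d.centre == (15.0, 5.0)  # (x, y) at the arc midpoint
    assert d.resampled.shape == (10, 2)


def test_descriptor_vertical_chain():
    chain = np.array([(r, 7) for r in range(0, 9)])
    d = path_descriptor(chain, L=10)
    assert d.orientation == pytest.approx(math.pi / 2)


def test_descriptor_diagonal_length():
    chain = np.array([(k, k) for k in range(6)])  # 5 diagonal steps
    d = path_descriptor(chain, L=10)
    assert d.length == pytest.approx(5 * math.sqrt(2))


def test_descriptor_orientation_folded():
    up = np.array([(r, r) for r in range(10)])
    down = up[::-1].copy()
    assert path_descriptor(up, 10).orientation == pytest.approx(
        path_descriptor(down, 10).orientation)
    assert 0 <= path_descriptor(up, 10).orientation < math.pi


def test_descriptor_single_pixel_degenerate():
    with pytest.raises(DegenerateSkeletonError):
        path_descriptor(np.array([[3, 3]]), L=10)


def test_descriptor_resampled_spans_chain():
    chain = np.array([(5, c) for c in range(0, 30)])
    d = path_descriptor(chain, L=10)
    assert d.resampled[0] == pytest.approx([0.0, 5.0])
    assert d.resampled[-1] == pytest.approx([29.0, 5.0])


# --------------------------------------------------------------------------
# assign_segments


def test_assign_x_opposite_arms():
    main, anti = _pixel_x()
    skel = graph_from_points(main + anti)
    segments = split_at_branchpoints(skel)
    l_main = 42 * math.sqrt(2)
    l_anti = 28 * math.sqrt(2)
    priors = [(1, l_main, (26.0, 26.0)), (2, l_anti, (26.0, 26.0))]
    res = assign_segments(segments, priors, SkeletonConfig())
    assert not res.fallback
    long_arms = {i for i, s in enumerate(segments) if chain_length(s) > 23}
    assert set(res.segments_per_worm[1]) == long_arms
    assert set(res.segments_per_worm[2]) == set(range(4)) - long_arms
    assert res.assembled_lengths[1] == pytest.approx(l_main, rel=0.05)
    assert res.assembled_lengths[2] == pytest.approx(l_anti, rel=0.05)


def test_assign_single_segment_end_to_end_split():
    seg = np.array([(30, c) for c in range(0, 101)])  # length 100
    priors = [(1, 60.0, (20.0, 30.0)), (2, 40.0, (80.0, 30.0))]
    res = assign_segments([seg], priors, SkeletonConfig())
    # brute-force oracle over all interior cut points
    best = min(min(abs(k - a) + abs((100 - k) - b)
                   for (a, b) in ((60, 40), (40, 60)))
               for k in range(1, 100))
    assert res.residual == pytest.approx(best, abs=1e-9)
    assert res.shared_segments == [0]
    lengths = sorted(res.assembled_lengths.values())
    assert lengths == pytest.approx([40.0, 60.0], abs=1.0)


def test_assign_single_segment_solo_claim():
    # chain matches one prior outright: no split
    seg = np.array([(30, c) for c in range(0, 61)])  # length 60
    priors = [(1, 60.0, (30.0, 30.0)), (2, 0.5, (90.0, 90.0))]
    res = assign_segments([seg], priors, SkeletonConfig())
    assert res.segments_per_worm[1] == [0]
    assert res.segments_per_worm[2] == []
    assert res.assembled_lengths[2] == 0.0


def test_assign_tiebreak_smaller_id_nearer_centre():
    seg_a = np.array([(0, c) for c in range(0, 21)])
    seg_b = np.array([(40, c) for c in range(0, 21)])
    priors = [(1, 20.0, (10.0, 0.0)), (2, 20.0, (10.0, 40.0))]
    res = assign_segments([seg_a, seg_b], priors, SkeletonConfig())
    assert res.segments_per_worm[1] == [0]
    assert res.segments_per_worm[2] == [1]
    assert res.residual == pytest.approx(0.0)


def test_assign_three_priors_fallback_by_centroid():
    segs = [np.array([(0, c) for c in range(0, 11)]),
            np.array([(20, c) for c in range(0, 11)]),
            np.array([(40, c) for c in range(0, 11)])]
    priors = [(1, 10.0, (5.0, 0.0)), (2, 10.0, (5.0, 20.0)),
              (3, 10.0, (5.0, 40.0))]
    res = assign_segments(segs, priors, SkeletonConfig())
    assert res.fallback
    assert res.segments_per_worm == {1: [0], 2: [1], 3: [2]}


def test_assign_no_segments_error():
    with pytest.raises(ValueError):
        assign_segments([], [(1, 10.0, (0.0, 0.0)), (2, 10.0, (1.0, 1.0))])


def test_assign_unchainable_pair_best_feasible_split():
    # two far-apart segments, priors demanding both on one worm
    seg_a = np.array([(0, c) for c in range(0, 11)])
    seg_b = np.array([(100, c) for c in range(0, 11)])
    priors = [(1, 20.0, (5.0, 0.0)), (2, 0.5, (5.0, 100.0))]
    res = assign_segments([seg_a, seg_b], priors, SkeletonConfig())
    # the pair cannot chain (gap 100 px >> connect_tol), so the best
    # feasible split gives one segment each
    assert sorted(len(v) for v in res.segments_per_worm.values()) == [1, 1]


def test_rendered_worm_skeleton_length_matches_state():
    state = straight_worm(100, 100, heading=0.3)
    blob = single_blob(worm_frame([state]))
    chain = longest_path_chain(skeletonize_blob(blob))
    assert chain_length(chain) == pytest.approx(state.length, rel=0.15)
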
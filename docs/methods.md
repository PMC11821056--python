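# Methods

This document describes each stage of the `wormflow` pipeline precisely
enough to re-derive the implementation, together with the rationale for
every default value.  Coordinates are 0-based pixels with `x` = column and
`y` = row; MOT CSV files are 1-based per the MOTChallenge convention.

## 1. Synthetic videos (`wormflow.synthetic`)

Each worm is an inextensible centreline of fixed arc length `L` whose
curvature varies sinusoidally along the body,
`κ(s) = A·sin(2πs/λ + phase)`; advancing `phase` by `phase_speed` rad/frame
produces the crawling undulation.  The amplitude `A` is derived from the
requested lateral envelope (`worm_width_px`, default 12) via the small-angle
relation `excursion ≈ A·(λ/2π)²`, so the posture's bounding thickness —
not the body stroke — matches the configured width.  The centreline is
rasterized and dilated with a radius-1 diamond to a ~3 px stroke, giving
single-worm areas of 150–250 px for the default 85 px length, below the
collision threshold `t_area = 300`.  Worm heading performs a bounded random
walk (`heading_sigma`), speed defaults to 4 px/frame (a ~1 mm worm crawling
at ~0.2 mm/s filmed at 4 fps and ~85 px/mm), and per-worm mean gray is
jittered ±10 around 60 on a background of 200 with σ=2 sensor noise and a
few sub-`min_area` static speckles.

Collisions are engineered, not left to chance: `round(collision_rate ·
n_frames / 100)` events are scheduled, each steering a chosen pair toward
each other's current centre for up to 25 frames, holding contact ≥ 3 frames,
then releasing.  Outside scheduled contact, a physicality veto keeps every
other worm pair separated: a pair may not come within 3 px (Euclidean
dilation) of touching, since the detector's morphological closing would
merge such near misses into one blob.  When a step would violate the veto,
the minimal set of offending worms is reverted to its previous pose with a
turn away from the partner; pairs already in contact are exempt so they can
separate.  Worm centres keep a margin of `1.05·L/2 + 8` px from the frame
border so bodies never clip (clipping would make ground-truth centroids
jump discontinuously).  Ground truth records every worm in every frame —
bounding box, centroid and body mask — including during collisions, and the
whole simulation is a pure function of its config (seed included).

## 2. Detection (`wormflow.detection`)

Frames are binarized with a local-mean adaptive threshold (block 51,
offset 15 gray levels: a pixel is foreground when darker than its local
mean by ≥ 15), followed by morphological opening then closing with a
radius-1 disk.  8-connected components of area ≥ `min_area` (50) become
`Blob` records sorted by bounding-box (top, left).  A blob is judged a
**collision** when its area strictly exceeds `t_area` (300) — a tie is
uncollided.  Border blobs are kept by default (`drop_border` available);
`invert` handles bright-on-dark footage.

## 3. Skeletons and collision splitting (`wormflow.skeleton`)

Blobs are thinned to 1-px skeletons (scikit-image `skeletonize` on a padded
crop, mapped back to global coordinates).  Skeleton pixels with ≥ 3
8-neighbours are branchpoints.  For splitting, the removal cluster is every
branchpoint plus any skeleton pixel adjacent to ≥ 2 branchpoints (this
suppresses 1–2 px stubs between nearby junctions); deleting it cuts the
skeleton into ordered segments, and segments shorter than `min_segment_px`
(3) are discarded as thinning debris.

Given the two implicated worms' **priors** — skeleton length and centre
recorded on their last pre-collision frame, frozen for the duration of the
contact — segments are distributed by exact search.  A subset of segments
is *chainable* if some ordering and flipping of its segments connects them
end to end with every junction gap ≤ `connect_tol` (6 px, the span of a
removed branchpoint cluster); the minimum-gap chaining per subset comes
from a dynamic program over (subset, last segment, free endpoint).  The
assembled length of a subset is the sum of its segment lengths plus its
junction gaps.  Candidate splits `(m1, m2)` are scored by the total
residual `|len(m1) − ℓ1| + |len(m2) − ℓ2|`; ties break toward fewer shared
segments, then toward placing the smaller worm id nearer its recorded
centre.  The search runs in two passes: first over exclusive splits
(`m2 = complement(m1)`); then, if no exclusive split exists or one leaves a
worm's residual above `shared_tol` (25%) of its prior length, over splits
where `m2` may additionally reuse any subset of `m1` — this covers the
worm-on-worm topology where one skeleton stretch belongs to both bodies.
Special cases: a single segment (end-to-end contact) is cut at the interior
point minimising the residual, unless one worm claiming the whole chain is
strictly better; > 12 segments keep the 12 longest in the exact search;
> 2 implicated worms or no chainable split fall back to a nearest-centroid
assignment flagged `fallback=True`.

Every worm chain gets a descriptor: arc length (axial steps 1, diagonal
√2), the arc-length midpoint as centre, an undirected orientation in
[0, π) through the midpoint and the geometrically nearer endpoint, and 10
arc-length-uniform resampled points.

## 4. Intra-trajectory association (`wormflow.intra`)

Adjacent-frame gating: detections in frames t and t+1 may link only when
centre distance `d ≤ dist_thr` (20 px) **and** folded orientation change
`ΔO ≤ angle_thr` (π/4) — both inclusive.  Among gate-passing pairs, a
bipartite assignment minimising total centre distance decides the links.
Chains of linked detections are cut into fixed `window`-frame fragments
(3); a broken chain emits its partial fragment.  Fragment velocity is
(last − first)/span; fragment appearance is the per-frame appearance
profile (below) averaged over its frames.

Collided blobs are handled before linking: a chain is *implicated* when its
constant-velocity predicted centre falls inside the blob's bbox dilated by
`dist_thr`.  With ≥ 2 implicated chains, the two nearest the blob centroid
are split via the skeleton method, each resulting detection carrying the
identity (`bound_chain_id`) of the prior that produced it; since
near-equal prior lengths make the length-based labelling arbitrary, the
two labels are swapped when the swapped pairing is closer to the chains'
predicted centres.  Bound detections re-attach to their chain directly
(subject to the distance gate), so identity survives multi-frame contacts.

## 5. Network-flow association (`wormflow.flow`)

Each fragment `i` becomes a split vertex `u_i → v_i` with detection cost
`c_det = −0.6`; the source feeds every `u_i` at `c_enter = 0.4`, every
`v_i` reaches the sink at `c_exit = 0.4`, and a transition edge `v_i → u_j`
exists when `1 ≤ t_start(j) − t_end(i) ≤ max_gap` and fragment i's
constant-velocity prediction lands within `dist_thr · gap` of fragment j's
start.  `max_gap` defaults to 3: detections exist in every frame (collided
blobs are split, not dropped), so genuine same-worm gaps come only from
short chain breaks, and longer edges would permit physically impossible
jumps between distant worms.  The entry/exit/detection magnitudes make a
fragment profitable to track as soon as its net path cost is negative
(0.4 + 0.4 − 0.6 = 0.2 per singleton, −0.6 + C_ij per extension with
C_ij ∈ [0, 1]), values standard for unit-capacity flow trackers.

Transition cost `C_ij = 0.5·C_a + 0.5·C_v`.  Appearance: each detection
samples mean grayscale in an M×M window (M=5) at its 10 resampled skeleton
points; profiles are normalised to unit sum and compared by
`C_a = 1 − Σ_l √(q_l c_l)` (the printed 1−BC form; a √(1−BC) variant is
switchable).  Velocity: `C_v = (1 − cos(v_i, v_j))/2`, with 0.5 for
near-zero speeds (no direction information).

All capacities are 1, so a k-unit integral min-cost flow decomposes into k
vertex-disjoint source-to-sink paths.  The solver runs successive shortest
augmenting paths on reduced costs (Dijkstra with node potentials seeded by
one topological relaxation of the initial DAG); per-path cost increments
are non-decreasing, so it stops at the first non-negative increment — that
flow value is the global optimum, possibly zero.  Cost ties break toward
the lexicographically smallest node sequence, making the output
deterministic.  Gaps inside a recovered trajectory are filled by linear
box interpolation when writing tracks.

## 6. Evaluation (`wormflow.evaluation`)

CLEAR-MOT with IoU matching at `iou_thr = 0.3` (0.5 is too strict for thin
elongated boxes).  Per frame, matches carried over from the previous frame
are kept while their IoU stays above threshold; the remainder is an optimal
assignment maximising total IoU over above-threshold pairs.  Unmatched
ground truth → FN, unmatched predictions → FP; a ground-truth track whose
matched hypothesis id differs from its most recent matched id → IDSW.
`MOTA = 1 − (FN + FP + IDSW)/GT` (may be negative);
`MOTP` = mean IoU over all matches (undefined without matches — reported
as null in JSON output).  Metrics are invariant to any consistent
relabelling of prediction ids.

## Default-value summary

| Parameter | Default | Rationale |
|---|---|---|
| `t_area` | 300 px² | above the 150–250 px single-worm area, below any two-worm union |
| `min_area` | 50 px² | rejects speckle impurities |
| `adaptive_block` / `offset` | 51 / 15 | window ≫ worm width; offset ≫ sensor noise σ=2 |
| `dist_thr` | 20 px | > 2× max per-frame displacement (speed ≤ ~5 px/frame) |
| `angle_thr` | π/4 | generous for undulating bodies, forbids cross-identity links |
| `window` | 3 frames | short fragments keep per-fragment purity high |
| `connect_tol` | 6 px | spans a removed branchpoint cluster |
| `shared_tol` | 0.25 | residual fraction that triggers shared-segment search |
| `w_a`, `w_v` | 0.5, 0.5 | equal-weight cost blend |
| `c_enter`, `c_exit`, `c_det` | 0.4, 0.4, −0.6 | real fragments pay for themselves |
| `max_gap` | 3 frames | per-frame detections make longer gaps unphysical |
| `mask_size` M | 5 px | covers the body stroke plus a margin of background |
| `n_skel` L | 10 | skeleton sample count for appearance profiles |
| `iou_thr` | 0.3 | suits thin elongated boxes |
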
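"""Centerline tracking: cost model, path optimality, recentering, steps."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mpcpr import phantom, tracking
from mpcpr.centerline import CenterlinePath, resample_per_slice
from mpcpr.errors import TrackingError, UsageError

WINDOW = (190.0, 2000.0)


# ---------------------------------------------------------------------------
# cost image
# ---------------------------------------------------------------------------

def test_cost_floor_inside_window(tube):
    _, vol, _ = tube
    cost = tracking.cost_image(vol, WINDOW, floor=1.0)
    assert cost[24, 24, 40] == 1.0  # lumen voxel, 400 HU
    assert cost[2, 2, 40] >= 10.0  # soft tissue 150 HU below the window
    assert np.all(cost > 0)


def test_cost_requires_ordered_window(tube):
    _, vol, _ = tube
    with pytest.raises(UsageError):
        tracking.cost_image(vol, (500.0, 100.0))


def test_low_cost_voxels_lie_in_true_lumen(tube):
    _, vol, truth = tube
    cost = tracking.cost_image(vol, WINDOW)
    for k in range(10, 70):
        i, j = np.unravel_index(np.argmin(cost[:, :, k]), cost.shape[:2])
        assert truth.lumen_mask[i, j, k]


# ---------------------------------------------------------------------------
# minimum-cost path
# ---------------------------------------------------------------------------

def _grid_graph(cost):
    G = nx.Graph()
    shape = cost.shape
    for i in np.ndindex(shape):
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            j = tuple(np.add(i, off))
            if all(0 <= v < s for v, s in zip(j, shape)):
                w = 0.5 * (cost[i] + cost[j]) * np.linalg.norm(off)
                G.add_edge(i, j, weight=w)
    return G


def _enumerate_optimum(cost, a, b):
    """Branch-and-bound DFS over all simple paths (tiny grids only)."""
    shape = cost.shape
    best = [np.inf]

    def visit(node, acc, seen):
        if acc >= best[0]:
            return
        if node == b:
            best[0] = acc
            return
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            nxt = tuple(np.add(node, off))
            if nxt in seen or not all(0 <= v < s for v, s in zip(nxt, shape)):
                continue
            w = 0.5 * (cost[node] + cost[nxt]) * np.linalg.norm(off)
            visit(nxt, acc + w, seen | {nxt})

    visit(a, 0.0, {a})
    return best[0]


def test_optimality_matches_exhaustive_enumeration(rng):
    for _ in range(3):
        cost = rng.uniform(0.5, 4.0, size=(3, 3, 4))
        p = tracking.min_cost_path(cost, (0, 0, 0), (2, 2, 3))
        got = tracking.path_cost(cost, p)
        ref = _enumerate_optimum(cost, (0, 0, 0), (2, 2, 3))
        assert got == pytest.approx(ref, abs=1e-9)


def test_optimality_matches_independent_dijkstra(rng):
    for _ in range(3):
        cost = rng.uniform(0.5, 5.0, size=(6, 6, 6))
        p = tracking.min_cost_path(cost, (0, 0, 0), (5, 5, 5))
        ref = nx.dijkstra_path_length(_grid_graph(cost), (0, 0, 0), (5, 5, 5))
        assert tracking.path_cost(cost, p) == pytest.approx(ref, abs=1e-9)


def test_path_cost_symmetric(rng):
    cost = rng.uniform(0.5, 5.0, size=(6, 6, 6))
    fwd = tracking.min_cost_path(cost, (0, 1, 0), (5, 4, 5))
    rev = tracking.min_cost_path(cost, (5, 4, 5), (0, 1, 0))
    assert tracking.path_cost(cost, fwd) == pytest.approx(
        tracking.path_cost(cost, rev), abs=1e-9)


def test_uniform_cost_gives_digital_straight_segment():
    cost = np.ones((9, 9, 9))
    p = tracking.min_cost_path(cost, (1, 2, 0), (7, 5, 8))
    steps = np.diff(p.points, axis=0)
    # 26-connected moves only, monotone toward the target, minimal step count
    assert np.all(np.abs(steps) <= 1)
    assert len(steps) == 8  # Chebyshev distance
    assert np.all(steps[:, 2] == 1)


def test_unreachable_barrier_raises_tracking_error():
    cost = np.ones((5, 5, 5))
    cost[:, :, 2] = np.inf
    with pytest.raises(TrackingError, match="unreachable"):
        tracking.min_cost_path(cost, (0, 0, 0), (4, 4, 4))


def test_occluded_tube_detours_into_parallel_vein():
    spec = phantom.straight_tube_spec(
        radius=1.5, shape=(48, 48, 80),
        lesions=[phantom.Lesion("occlusion", "TUBE", 31.0, 10.0)],
    )
    spec.vein_overlay = phantom.VeinOverlay(artery="TUBE", offset=(6.0, 0.0))
    vol, _ = phantom.generate_phantom(spec)
    model = spec.resolved_tree()
    cost = tracking.cost_image(vol, WINDOW)
    p = tracking.min_cost_path(cost, model.root, model.branches["TUBE"].points[-1],
                               vol.spacing, vol.origin)
    assert p.points[:, 0].max() >= 28.0  # reaches the vein at x = 30


# ---------------------------------------------------------------------------
# recentering
# ---------------------------------------------------------------------------

def _offset_axis_path(truth, dx):
    tp = truth.centerlines.paths["tube"]
    pts = tp.points.copy()
    pts[:, 0] += dx
    return CenterlinePath("seed", pts, resampled=False)


def test_recenter_recovers_axis_from_offset_seed(tube):
    _, vol, truth = tube
    rec = tracking.recenter(vol, _offset_axis_path(truth, 2.0), 220.0)
    tp = truth.centerlines.paths["tube"]
    for k in range(int(rec.slice_indices[0]), int(rec.slice_indices[-1]) + 1):
        got, want = rec.point_at_slice(k), tp.point_at_slice(k)
        if want is None:
            continue
        assert np.linalg.norm(got[:2] - want[:2]) <= 0.5  # half in-plane spacing


def test_recenter_axis_path_is_fixed_point(tube):
    _, vol, truth = tube
    tp = truth.centerlines.paths["tube"]
    rec = tracking.recenter(vol, CenterlinePath("axis", tp.points.copy()), 220.0)
    for k in range(int(rec.slice_indices[0]), int(rec.slice_indices[-1]) + 1):
        want = tp.point_at_slice(k)
        if want is not None:
            assert np.linalg.norm(rec.point_at_slice(k)[:2] - want[:2]) <= 0.15


def test_recenter_never_degrades_mean_axis_distance(tube):
    _, vol, truth = tube
    tp = truth.centerlines.paths["tube"]
    for dx in (0.5, 1.5, 2.5):
        seed = _offset_axis_path(truth, dx)
        rec = tracking.recenter(vol, seed, 220.0)
        before = dx
        devs = [
            np.linalg.norm(rec.point_at_slice(k)[:2] - tp.point_at_slice(k)[:2])
            for k in range(int(rec.slice_indices[0]), int(rec.slice_indices[-1]) + 1)
            if tp.point_at_slice(k) is not None
        ]
        assert np.mean(devs) <= before + 1e-9


def test_recenter_flags_occluded_extent():
    spec = phantom.straight_tube_spec(
        radius=3.0, lesions=[phantom.Lesion("occlusion", "TUBE", 30.0, 10.0)]
    )
    vol, truth = phantom.generate_phantom(spec)
    tp = truth.centerlines.paths["tube"]
    rec = tracking.recenter(vol, CenterlinePath("axis", tp.points.copy()), 220.0)
    expected = 10.0 / vol.spacing[2]
    assert abs(int(rec.flagged.sum()) - expected) <= 1


# ---------------------------------------------------------------------------
# tree assembly
# ---------------------------------------------------------------------------

def test_tree_from_root_and_six_endpoints_tracks_within_one_voxel(two_leg):
    spec, vol, truth = two_leg
    model = spec.resolved_tree()
    endpoints = ("L_dorsal_pedal", "L_plantar", "L_peroneal",
                 "R_dorsal_pedal", "R_plantar", "R_peroneal")
    cps = {n: [model.root, truth.centerlines.paths[n].points[-1]]
           for n in endpoints}
    tree = tracking.build_tree(vol, cps, enhancement_window=WINDOW)
    assert set(tree.paths) == set(endpoints)
    for name in endpoints:
        p, tp = tree.paths[name], truth.centerlines.paths[name]
        k0 = max(p.slice_indices[0], tp.slice_indices[0])
        k1 = min(p.slice_indices[-1], tp.slice_indices[-1])
        devs = [p.point_at_slice(k) - tp.point_at_slice(k) for k in range(k0, k1 + 1)]
        rms = np.sqrt(np.mean(np.sum(np.square(devs), axis=1)))
        assert rms <= 1.0, f"{name}: RMS {rms:.2f} mm"


def test_occlusion_bridged_by_mid_occlusion_control_point():
    spec = phantom.straight_tube_spec(
        radius=3.0, lesions=[phantom.Lesion("occlusion", "TUBE", 31.0, 10.0)]
    )
    vol, truth = phantom.generate_phantom(spec)
    model = spec.resolved_tree()
    mid = np.array([24.0, 24.0, 40.0])
    tree = tracking.build_tree(
        vol, {"tube": [model.root, mid, model.branches["TUBE"].points[-1]]},
        enhancement_window=WINDOW,
    )
    p, tp = tree.paths["tube"], truth.centerlines.paths["tube"]
    k0 = max(p.slice_indices[0], tp.slice_indices[0])
    k1 = min(p.slice_indices[-1], tp.slice_indices[-1])
    devs = [p.point_at_slice(k) - tp.point_at_slice(k) for k in range(k0, k1 + 1)]
    assert np.sqrt(np.mean(np.sum(np.square(devs), axis=1))) <= 1.0


def test_degenerate_control_points_rejected(tube):
    _, vol, _ = tube
    root = [24.0, 24.0, 2.0]
    with pytest.raises(UsageError, match="distinct"):
        tracking.build_tree(vol, {"tube": [root, root]}, enhancement_window=WINDOW)
    with pytest.raises(UsageError, match="common root"):
        tracking.build_tree(
            vol,
            {"a": [[24, 24, 2], [24, 24, 70]], "b": [[30, 24, 2], [24, 24, 70]]},
            enhancement_window=WINDOW,
        )


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

def _straight_resampled(n=30):
    pts = np.stack([np.full(n, 10.0), np.full(n, 10.0), np.arange(n, dtype=float)], 1)
    return CenterlinePath("p", pts, resampled=True, slice_indices=np.arange(n))


def test_straight_path_has_no_steps():
    assert tracking.detect_steps(_straight_resampled(), 3.0) == []


def test_single_inserted_jump_detected_at_its_slice():
    p = _straight_resampled()
    p.points[15:, 0] += 6.0  # 6 mm lateral jump between slices 14 and 15
    steps = tracking.detect_steps(p, 3.0)
    assert len(steps) == 1
    assert steps[0].slice_index == 15
    assert steps[0].jump_mm == pytest.approx(6.0)


def test_vein_overlay_without_bridge_produces_step_formations():
    spec = phantom.straight_tube_spec(
        radius=1.5, shape=(48, 48, 80),
        lesions=[phantom.Lesion("occlusion", "TUBE", 31.0, 10.0)],
    )
    spec.vein_overlay = phantom.VeinOverlay(artery="TUBE", offset=(6.0, 0.0))
    vol, _ = phantom.generate_phantom(spec)
    model = spec.resolved_tree()
    end = model.branches["TUBE"].points[-1]
    tree = tracking.build_tree(vol, {"tube": [model.root, end]},
                               enhancement_window=WINDOW)
    steps = tracking.detect_steps(tree.paths["tube"], 3.0)
    # occlusion spans arclength 31-41 on a tube starting at z=4
    assert any(33 <= s.slice_index <= 47 for s in steps)
    # with a bridging control point the artery course is kept: no steps
    tree2 = tracking.build_tree(
        vol, {"tube": [model.root, np.array([24.0, 24.0, 40.0]), end]},
        enhancement_window=WINDOW,
    )
    assert tracking.detect_steps(tree2.paths["tube"], 3.0) == []


def test_resample_per_slice_takes_first_crossing():
    pts = np.array([[0, 0, 0.0], [0, 0, 3.0], [5, 0, 1.0], [5, 0, 6.0]])
    p = resample_per_slice(pts, origin_z=0.0, spacing_z=1.0)
    assert np.all(np.diff(p.points[:, 2]) == 1.0)
    assert p.point_at_slice(2)[0] == 0.0  # first crossing of z=2 is on the first ascent
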
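"""Renderers: geometry contracts, HU conservation, oracle equivalence."""

import numpy as np
import pytest

from mpcpr import phantom, render
from mpcpr.centerline import CenterlinePath, CenterlineTree
from mpcpr.errors import RenderError, UsageError
from mpcpr.volume import Volume

from conftest import brute_trilinear


# ---------------------------------------------------------------------------
# rotation angles
# ---------------------------------------------------------------------------

def test_default_rotation_series_geometry():
    angles = render.rotation_angles(180, 9)
    assert len(angles) == 21
    assert angles[0] == -90.0
    assert angles[-1] == 90.0
    assert np.allclose(np.diff(angles), 9.0)


def test_rotation_angles_coarse():
    assert render.rotation_angles(180, 90) == [-90.0, 0.0, 90.0]


def test_rotation_angles_requires_divisible_step():
    with pytest.raises(UsageError, match="divide"):
        render.rotation_angles(180, 7)


# ---------------------------------------------------------------------------
# single-path CPR
# ---------------------------------------------------------------------------

def test_straight_tube_cpr_equals_coronal_reslice(tube):
    _, vol, truth = tube
    tp = truth.centerlines.paths["tube"]
    img = render.render_cpr(vol, tp, 0.0, halfwidth_mm=10.0)
    assert img.shape[0] == vol.n_slices
    rows = np.arange(tp.slice_indices[0], tp.slice_indices[-1] + 1)
    reslice = vol.voxels[24 - 10:24 + 11, 24, :].T  # coronal plane through the axis
    np.testing.assert_array_equal(img.pixels[rows], reslice[rows])


def test_cpr_rotational_invariance_on_smooth_cylinder():
    vol, axis = phantom.smooth_cylinder_volume(shape=(96, 96, 40),
                                               spacing=(0.5, 0.5, 1.0))
    path = CenterlinePath("axis", axis, resampled=True,
                          slice_indices=np.arange(vol.n_slices))
    ref = render.render_cpr(vol, path, -90.0, 10.0)
    for ang in render.rotation_angles(180, 9)[1:]:
        img = render.render_cpr(vol, path, ang, 10.0)
        assert np.abs(img.pixels - ref.pixels).max() <= 0.5


def test_cpr_matches_brute_force_sampler(rng):
    vol = Volume(rng.uniform(-500, 2000, (8, 8, 8)).astype(np.float32), (1, 1, 1))
    k = np.arange(1, 7)
    pts = np.stack([3.0 + 0.3 * k, 4.0 - 0.2 * k, k.astype(float)], axis=1)
    path = CenterlinePath("p", pts, resampled=True, slice_indices=k)
    img = render.render_cpr(vol, path, 33.0, halfwidth_mm=2.0)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if img.attribution[r, c] == render.CONTEXT:
                continue
            want = brute_trilinear(vol.voxels, vol.spacing, vol.origin,
                                   img.sample_points[r, c])
            assert img.pixels[r, c] == pytest.approx(want, abs=1e-3)


def test_cpr_path_outside_volume_reports_slices(tube):
    _, vol, truth = tube
    pts = truth.centerlines.paths["tube"].points.copy()
    pts[-3:, 0] += 100.0
    bad = CenterlinePath("p", pts, resampled=True,
                         slice_indices=truth.centerlines.paths["tube"].slice_indices)
    with pytest.raises(RenderError, match="slices"):
        render.render_cpr(vol, bad, 0.0, 10.0)


# ---------------------------------------------------------------------------
# multipath CPR
# ---------------------------------------------------------------------------

def _two_tube_scene():
    shape = (64, 48, 60)
    vox = np.full(shape, 40.0, np.float32)
    X, Y = np.meshgrid(np.arange(shape[0], dtype=float),
                       np.arange(shape[1], dtype=float), indexing="ij")
    for xc in (22.0, 42.0):
        cov = np.clip(4.0 - np.hypot(X - xc, Y - 24.0) + 0.5, 0, 1)
        vox = vox * (1 - cov[:, :, None]) + 400.0 * cov[:, :, None]
    vol = Volume(vox.astype(np.float32), (1.0, 1.0, 1.0))
    k = np.arange(shape[2])
    mk = lambda name, xc: CenterlinePath(
        name, np.stack([np.full(len(k), xc), np.full(len(k), 24.0), k * 1.0], 1),
        resampled=True, slice_indices=k)
    tree = CenterlineTree(root=[22, 24, 0],
                          paths={"A": mk("A", 22.0), "B": mk("B", 42.0)})
    return vol, tree


def test_mpcpr_partitions_columns_at_midline():
    vol, tree = _two_tube_scene()
    img = render.render_mpcpr(vol, tree, 0.0, halfwidth_mm=10.0, context="none")
    xs = img.meta["screen_columns"]
    att = img.attribution[30]
    for c, x in enumerate(xs):
        if 12.0 <= x < 32.0:
            assert att[c] == 0
        elif 32.0 < x <= 52.0:
            assert att[c] == 1
        elif x < 12.0 or x > 52.0:
            assert att[c] == render.CONTEXT
    # tie at the exact midline goes to the leftmost-on-screen path
    assert att[int(np.searchsorted(xs, 32.0))] == 0


def test_mpcpr_lumen_columns_equal_single_path_cpr():
    vol, tree = _two_tube_scene()
    img = render.render_mpcpr(vol, tree, 0.0, halfwidth_mm=8.0, context="none")
    xs = img.meta["screen_columns"]
    for name, xc in (("A", 22.0), ("B", 42.0)):
        cpr = render.render_cpr(vol, tree.paths[name], 0.0, halfwidth_mm=8.0)
        c0 = int(np.searchsorted(xs, xc - 8.0))
        np.testing.assert_array_equal(img.pixels[:, c0:c0 + 17], cpr.pixels)


def test_mpcpr_single_path_tree_reduces_to_cpr(tube):
    _, vol, truth = tube
    tp = truth.centerlines.paths["tube"]
    tree = CenterlineTree(root=tp.points[0], paths={"tube": tp})
    img = render.render_mpcpr(vol, tree, 0.0, halfwidth_mm=10.0, context="none")
    cpr = render.render_cpr(vol, tp, 0.0, halfwidth_mm=10.0)
    xs = img.meta["screen_columns"]
    c0 = int(np.searchsorted(xs, 24.0 - 10.0))
    owned = img.attribution[:, c0:c0 + 21] == 0
    np.testing.assert_array_equal(img.pixels[:, c0:c0 + 21][owned],
                                  cpr.pixels[owned])


def test_mpcpr_row_count_equals_slice_count(two_leg):
    spec, vol, truth = two_leg
    img = render.render_mpcpr(vol, truth.centerlines, -18.0, context="none")
    assert img.shape[0] == vol.n_slices


# ---------------------------------------------------------------------------
# bone segmentation and MIP
# ---------------------------------------------------------------------------

def _bone_scene():
    spec = phantom.straight_tube_spec(radius=4.0, shape=(64, 48, 60))
    rod = phantom.VesselBranch("FEMUR", np.array([[48.0, 24.0, 2.0],
                                                  [48.0, 24.0, 58.0]]), 6.0)
    spec.bones = [rod]
    return phantom.generate_phantom(spec)


def test_bone_mask_covers_bone_not_lumen():
    vol, truth = _bone_scene()
    mask = render.segment_bones(vol, hu_threshold=700.0, min_component_voxels=64)
    covered = mask[truth.bone_mask].mean()
    lumen_hit = mask[truth.lumen_mask].mean()
    assert covered >= 0.95
    assert lumen_hit < 0.01


def test_bone_mask_empty_above_max_hu(tube):
    _, vol, _ = tube
    assert not render.segment_bones(vol, hu_threshold=5000.0).any()


def test_small_high_hu_component_excluded(tube):
    _, vol, _ = tube
    vox = vol.voxels.copy()
    vox[5:7, 5:7, 5:7] = 2000.0  # 8 voxels, below the size filter
    small = Volume(vox, vol.spacing, vol.origin)
    assert not render.segment_bones(small, 700.0, min_component_voxels=64).any()


def test_constant_volume_mip_is_constant():
    vol = Volume(np.full((12, 10, 8), 40.0, np.float32), (1, 1, 1))
    img = render.render_mip(vol, None, 25.0)
    assert np.all(img.pixels == pytest.approx(40.0, abs=1e-3))


def test_mip_matches_brute_force_ray_max(rng):
    vol = Volume(rng.uniform(-100, 1000, (8, 8, 8)).astype(np.float32), (1, 1, 1))
    mask = np.zeros((8, 8, 8), bool)
    mask[2:4, 2:4, :] = True
    img = render.render_mip(vol, mask, 33.0)
    u, v = render.view_vectors(33.0)
    xs = img.meta["screen_columns"]
    corners = np.array([[x, y, 0.0] for x in (0, 7) for y in (0, 7)])
    d = corners @ v
    ds = np.arange(d.min(), d.max() + 0.25, 0.5)
    for k in range(8):
        for c in range(0, len(xs), 3):
            best = -np.inf
            for dd in ds:
                p = xs[c] * u + dd * v
                # rays are clamped to the volume support, like the renderer
                p = np.clip([p[0], p[1], float(k)], 0.0, 7.0)
                ii = np.round(p).astype(int)
                if mask[tuple(ii)]:
                    continue
                best = max(best, brute_trilinear(vol.voxels, (1, 1, 1), (0, 0, 0), p))
            if best == -np.inf:
                best = -1024.0
            assert img.pixels[k, c] == pytest.approx(best, abs=1e-3)


def test_mip_blinded_by_calcification_where_mpcpr_shows_lumen():
    spec = phantom.straight_tube_spec(
        radius=4.0, shape=(48, 48, 60),
        lesions=[phantom.Lesion("calcification", "TUBE", 20.0, 12.0)],
    )
    vol, truth = phantom.generate_phantom(spec)
    tp = truth.centerlines.paths["tube"]
    tree = CenterlineTree(root=tp.points[0], paths={"tube": tp})
    mip = render.render_mip(vol, None, 0.0)
    mp = render.render_mpcpr(vol, tree, 0.0, halfwidth_mm=8.0, context="none")
    # a lumen column slightly off-axis, inside the calcified extent (z ~ 28-34)
    xs_mip = mip.meta["screen_columns"]
    xs_mp = mp.meta["screen_columns"]
    c_mip = int(np.searchsorted(xs_mip, 26.0))
    c_mp = int(np.searchsorted(xs_mp, 26.0))
    z = 30
    assert mip.pixels[z, c_mip] >= 700.0  # crescent dominates the ray
    assert abs(mp.pixels[z, c_mp] - 400.0) < 60.0  # mpCPR keeps the lumen HU


def test_mip_with_empty_mask_equals_unmasked(tube):
    _, vol, _ = tube
    a = render.render_mip(vol, None, 12.0)
    b = render.render_mip(vol, np.zeros(vol.shape, bool), 12.0)
    np.testing.assert_array_equal(a.pixels, b.pixels)


# ---------------------------------------------------------------------------
# series + symmetry
# ---------------------------------------------------------------------------

def test_series_has_21_stamped_views(tube):
    _, vol, truth = tube
    tp = truth.centerlines.paths["tube"]
    tree = CenterlineTree(root=tp.points[0], paths={"tube": tp})
    imgs = render.render_series(vol, tree, "mpcpr", halfwidth_mm=6.0,
                                context="none")
    assert len(imgs) == 21
    assert [im.angle for im in imgs] == render.rotation_angles(180, 9)
    assert all(im.shape[0] == vol.n_slices for im in imgs)


def test_mirrored_scene_renders_mirrored_image():
    vol, tree = _two_tube_scene()
    # column spacing chosen commensurate with the projected extent so the
    # mirrored screen grid lands on the same abscissas
    u, _ = render.view_vectors(27.0)
    extent = 63.0 * u[0] + 47.0 * u[1]
    cs = extent / 78.0
    img_pos = render.render_mpcpr(vol, tree, 27.0, halfwidth_mm=8.0, context="none",
                                  col_spacing=cs)
    # mirror volume and tree in x about the volume centre
    mvox = vol.voxels[::-1].copy()
    mvol = Volume(mvox, vol.spacing, vol.origin)
    xc = (vol.shape[0] - 1) * vol.spacing[0]
    mpaths = {}
    for name, p in tree.paths.items():
        pts = p.points.copy()
        pts[:, 0] = xc - pts[:, 0]
        mpaths[name] = CenterlinePath(name, pts, resampled=True,
                                      slice_indices=p.slice_indices.copy())
    mtree = CenterlineTree(root=[xc - 22, 24, 0], paths=mpaths)
    img_neg = render.render_mpcpr(mvol, mtree, -27.0, halfwidth_mm=8.0,
                                  context="none", col_spacing=cs)
    np.testing.assert_allclose(img_neg.pixels[:, ::-1], img_pos.pixels, atol=1e-2)
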
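"""CPR / multipath-CPR / MIP rendering as projected reformations.

All renderers share the viewing geometry: a viewing angle in
``[-90, +90]`` degrees (-90 right-lateral, 0 anteroposterior, +90
left-lateral) rotating about the cranio-caudal (z) axis.  The screen-x
unit vector is ``u = (cos a, sin a, 0)`` and the viewing-ray direction is
``v = (-sin a, cos a, 0)``.  Reformations are *projected*: row index ==
slice index, preserving true z distances at the full slice resolution of
the source volume (a 2000-slice dataset yields 2000-row reformations).
Every attributed pixel is a trilinear sample of the source volume; HU are
never remapped.  Out-of-volume samples read -1024 HU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from mpcpr.centerline import CenterlinePath, CenterlineTree
from mpcpr.errors import RenderError, UsageError
from mpcpr.volume import Volume

OUTSIDE_HU = -1024.0
CONTEXT = -1  # attribution index for pixels not owned by any path

DEFAULT_HALFWIDTH_MM = 10.0
DEFAULT_SLAB_MM = 20.0


@dataclass
class ReformattedImage:
    """A 2-D reformation: rows = axial slices, columns = lateral samples.

    ``attribution`` holds, per pixel, the index into ``labels`` of the
    centerline path that produced it, or -1 for context pixels.
    ``sample_points`` records the 3-D world position each attributed pixel
    was sampled at (NaN for context), so HU conservation can be audited
    against an independent sampler.
    """

    pixels: np.ndarray
    angle: float
    row_spacing: float
    col_spacing: float
    labels: list[str] = field(default_factory=list)
    attribution: np.ndarray | None = None
    sample_points: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def check_angle(angle: float) -> float:
    a = float(angle)
    if not -90.0 <= a <= 90.0:
        raise UsageError(f"viewing angle must lie in [-90, +90] deg, got {a}")
    return a


def view_vectors(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(screen-x unit u, viewing-ray unit v) for a viewing angle in degrees."""
    a = np.deg2rad(check_angle(angle_deg))
    u = np.array([np.cos(a), np.sin(a), 0.0])
    v = np.array([-np.sin(a), np.cos(a), 0.0])
    return u, v


def rotation_angles(range_deg: float = 180.0, step_deg: float = 9.0) -> list[float]:
    """Inclusive symmetric angle sequence: -range/2 ... +range/2 by step."""
    if step_deg <= 0:
        raise UsageError("step must be > 0")
    k = range_deg / step_deg
    if abs(k - round(k)) > 1e-9:
        raise UsageError(f"step {step_deg} does not divide the range {range_deg}")
    k = int(round(k))
    return [-range_deg / 2.0 + i * step_deg for i in range(k + 1)]


# ---------------------------------------------------------------------------
# shared geometry helpers
# ---------------------------------------------------------------------------

def _corners(vol: Volume) -> np.ndarray:
    lo = np.asarray(vol.origin, float)
    hi = lo + (np.asarray(vol.shape, float) - 1.0) * np.asarray(vol.spacing, float)
    return np.array([[x, y, 0.0] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])])


def _screen_columns(vol: Volume, u: np.ndarray, col_spacing: float) -> np.ndarray:
    """Global screen-abscissa grid covering the projected volume extent.

    Anchored at the minimum corner projection, so at angle 0 the columns
    coincide with the voxel x-centres when ``col_spacing == spacing[0]``.
    """
    a = _corners(vol) @ u
    ncols = int(np.floor((a.max() - a.min()) / col_spacing + 1e-9)) + 1
    return a.min() + np.arange(ncols) * col_spacing


def _trilinear(vol: Volume, world: np.ndarray) -> np.ndarray:
    """Trilinear samples of the volume at (..., 3) world positions."""
    idx = (world - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    flat = idx.reshape(-1, 3).T
    vals = ndimage.map_coordinates(vol.voxels, flat, order=1, mode="constant",
                                   cval=OUTSIDE_HU)
    return vals.reshape(world.shape[:-1])


def _default_col_spacing(vol: Volume) -> float:
    return float(min(vol.spacing[0], vol.spacing[1]))


def _path_row_table(vol: Volume, paths: list[CenterlinePath]) -> np.ndarray:
    """(P, n_slices, 3) path point per slice, NaN where a path is absent."""
    tab = np.full((len(paths), vol.n_slices, 3), np.nan)
    for p, path in enumerate(paths):
        if not path.resampled:
            raise UsageError(f"path {path.name!r} must be resampled to slices")
        k0 = int(path.slice_indices[0])
        k1 = int(path.slice_indices[-1])
        lo, hi = max(k0, 0), min(k1, vol.n_slices - 1)
        if hi >= lo:
            tab[p, lo:hi + 1] = path.points[lo - k0:hi - k0 + 1]
    return tab


# ---------------------------------------------------------------------------
# single-path CPR
# ---------------------------------------------------------------------------

def render_cpr(
    vol: Volume,
    path: CenterlinePath,
    angle: float,
    halfwidth_mm: float = DEFAULT_HALFWIDTH_MM,
    col_spacing: float | None = None,
) -> ReformattedImage:
    """Projected CPR of a single path.

    For each slice the volume is sampled along the in-plane line through
    the path point at that slice, perpendicular to the viewing direction,
    centred on the path point with extent +-halfwidth.  Rows without a
    path point are context (-1024).
    """
    if halfwidth_mm <= 0:
        raise UsageError("halfwidth must be > 0")
    u, _ = view_vectors(angle)
    cs = col_spacing or _default_col_spacing(vol)
    tab = _path_row_table(vol, [path])[0]
    present = ~np.isnan(tab[:, 0])
    if not present.any():
        raise RenderError(f"path {path.name!r} does not intersect the volume slices")
    inside = vol.contains_world(path.points)
    if not inside.all():
        bad = [int(k) for k in np.asarray(path.slice_indices)[~inside]]
        raise RenderError(f"path {path.name!r} leaves the volume at slices {bad}")
    m = int(round(halfwidth_mm / cs))
    offs = (np.arange(2 * m + 1) - m) * cs
    nrows = vol.n_slices
    pixels = np.full((nrows, 2 * m + 1), OUTSIDE_HU, dtype=np.float32)
    attribution = np.full((nrows, 2 * m + 1), CONTEXT, dtype=np.int16)
    sample_points = np.full((nrows, 2 * m + 1, 3), np.nan, dtype=np.float32)
    rows = np.nonzero(present)[0]
    pos = tab[rows][:, None, :] + offs[None, :, None] * u  # (R, C, 3)
    pixels[rows] = _trilinear(vol, pos).astype(np.float32)
    attribution[rows] = 0
    sample_points[rows] = pos
    return ReformattedImage(
        pixels=pixels, angle=float(angle), row_spacing=vol.spacing[2],
        col_spacing=cs, labels=[path.name], attribution=attribution,
        sample_points=sample_points, meta={"mode": "cpr", "halfwidth_mm": halfwidth_mm},
    )


# ---------------------------------------------------------------------------
# multipath CPR
# ---------------------------------------------------------------------------

def render_mpcpr(
    vol: Volume,
    tree: CenterlineTree,
    angle: float,
    halfwidth_mm: float = DEFAULT_HALFWIDTH_MM,
    context: str = "slab_mip",
    slab_mm: float = DEFAULT_SLAB_MM,
    col_spacing: float | None = None,
) -> ReformattedImage:
    """Multipath CPR: all root-to-endpoint paths composed into one image.

    Screen columns (a fixed global abscissa grid under the viewing
    rotation) are partitioned among the paths by nearest projected
    centerline abscissa; each owned column is CPR-sampled from its path's
    point, columns farther than halfwidth from every path show context
    (``"none"`` -> -1024, ``"slab_mip"`` -> a thin-slab MIP centred on the
    nearest path's depth).  The on-screen left/right ordering of the legs
    follows the projection at the given angle.
    """
    if context not in ("none", "slab_mip"):
        raise UsageError(f"unknown context mode {context!r}")
    u, v = view_vectors(angle)
    cs = col_spacing or _default_col_spacing(vol)
    labels = list(tree.paths)
    paths = [tree.paths[n] for n in labels]
    if not paths:
        raise UsageError("tree has no paths")
    tab = _path_row_table(vol, paths)  # (P, Z, 3)
    xs = _screen_columns(vol, u, cs)
    nrows, ncols = vol.n_slices, len(xs)

    absc = tab[:, :, 0] * u[0] + tab[:, :, 1] * u[1]  # (P, Z)
    _warn_overlapping(absc, tab, labels, cs)
    dist = np.abs(xs[None, None, :] - absc[:, :, None])  # (P, Z, C)
    dist = np.where(np.isnan(dist), np.inf, dist)
    winner = np.argmin(dist, axis=0)  # (Z, C)
    windist = np.take_along_axis(dist, winner[None], axis=0)[0]  # (Z, C)
    owned = windist <= halfwidth_mm

    pixels = np.full((nrows, ncols), OUTSIDE_HU, dtype=np.float32)
    attribution = np.full((nrows, ncols), CONTEXT, dtype=np.int16)
    sample_points = np.full((nrows, ncols, 3), np.nan, dtype=np.float32)

    zz, cc = np.nonzero(owned)
    if len(zz):
        w = winner[zz, cc]
        base = tab[w, zz]  # (N, 3)
        t = xs[cc] - absc[w, zz]
        pos = base + t[:, None] * u
        pixels[zz, cc] = _trilinear(vol, pos).astype(np.float32)
        attribution[zz, cc] = w.astype(np.int16)
        sample_points[zz, cc] = pos

    if context == "slab_mip":
        zz, cc = np.nonzero(~owned)
        if len(zz):
            w = winner[zz, cc]
            have = np.isfinite(absc[w, zz])
            depth = np.where(
                have,
                tab[w, zz, 0] * v[0] + tab[w, zz, 1] * v[1],
                _volume_center_depth(vol, v),
            )
            steps = np.arange(-slab_mm / 2.0, slab_mm / 2.0 + cs / 4.0, cs / 2.0)
            zw = vol.slice_world_z(zz)
            pos = (
                xs[cc][:, None, None] * u[None, None, :]
                + (depth[:, None] + steps[None, :])[..., None] * v[None, None, :]
            )
            pos[..., 2] = zw[:, None]
            vals = _trilinear(vol, pos)  # (N, S)
            pixels[zz, cc] = vals.max(axis=1).astype(np.float32)

    return ReformattedImage(
        pixels=pixels, angle=float(angle), row_spacing=vol.spacing[2],
        col_spacing=cs, labels=labels, attribution=attribution,
        sample_points=sample_points,
        meta={"mode": "mpcpr", "halfwidth_mm": halfwidth_mm, "context": context,
              "screen_columns": xs},
    )


def _volume_center_depth(vol: Volume, v: np.ndarray) -> float:
    c = np.asarray(vol.origin) + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing) / 2.0
    return float(c[0] * v[0] + c[1] * v[1])


def _warn_overlapping(absc: np.ndarray, tab: np.ndarray, labels: list[str],
                      cs: float) -> None:
    P = absc.shape[0]
    for i in range(P):
        for j in range(i + 1, P):
            both = np.isfinite(absc[i]) & np.isfinite(absc[j])
            # a shared trunk is not an overlap: only count slices where the
            # two paths actually run through different anatomy
            both &= np.linalg.norm(np.nan_to_num(tab[i] - tab[j]), axis=1) > 1e-6
            if both.sum() == 0:
                continue
            close = np.abs(absc[i, both] - absc[j, both]) < cs / 2.0
            if close.mean() > 0.5:
                warnings.warn(
                    f"paths {labels[i]!r} and {labels[j]!r} project onto the same "
                    "screen abscissa over most of their course (near-lateral view); "
                    "their columns cannot be separated at this angle",
                    stacklevel=3,
                )


# ---------------------------------------------------------------------------
# bone segmentation + MIP
# ---------------------------------------------------------------------------

def segment_bones(
    vol: Volume,
    hu_threshold: float = 700.0,
    min_component_voxels: int = 64,
    dilation_voxels: int = 1,
) -> np.ndarray:
    """Semiautomated bone mask: threshold, size-filtered components, closing.

    The mask is dilated by one voxel by default so that the partial-volume
    rim of cortical bone is suppressed too; without it the rim survives the
    HU threshold cut and leaves bright halos in the bone-suppressed MIP.
    """
    raw = np.asarray(vol.voxels) >= hu_threshold
    if not raw.any():
        return np.zeros(vol.shape, dtype=bool)
    lab = cc_label(raw, connectivity=3)
    counts = np.bincount(lab.ravel())
    keep = np.zeros(len(counts), dtype=bool)
    keep[1:] = counts[1:] >= min_component_voxels
    mask = keep[lab]
    if mask.any():
        struct = np.ones((3, 3, 3), bool)
        mask = ndimage.binary_closing(mask, structure=struct)
        for _ in range(dilation_voxels):
            mask = ndimage.binary_dilation(mask, structure=struct)
    return mask


def render_mip(
    vol: Volume,
    mask: np.ndarray | None,
    angle: float,
    col_spacing: float | None = None,
    depth_step: float | None = None,
    _chunk: int = 16,
) -> ReformattedImage:
    """Per-slice maximum intensity projection with bone voxels excluded.

    For each slice and screen column the maximum HU along the viewing ray
    is taken over trilinear samples, skipping samples that fall inside the
    (nearest-neighbour sampled) bone mask.  Ray samples are clamped to the
    volume support (a maximum must not be diluted by out-of-volume
    padding), so a constant volume projects to a constant image.
    """
    if mask is not None and tuple(mask.shape) != tuple(vol.shape):
        raise UsageError("bone mask shape must equal the volume shape")
    u, v = view_vectors(angle)
    cs = col_spacing or _default_col_spacing(vol)
    step = depth_step or cs / 2.0
    xs = _screen_columns(vol, u, cs)
    d = _corners(vol) @ v
    ds = np.arange(d.min(), d.max() + step / 2.0, step)
    nrows, ncols, nsteps = vol.n_slices, len(xs), len(ds)
    pixels = np.empty((nrows, ncols), dtype=np.float32)
    sample_points = np.full((nrows, ncols, 3), np.nan, dtype=np.float32)
    inplane = xs[:, None, None] * u[None, None, :] + ds[None, :, None] * v[None, None, :]
    mask_u8 = None if mask is None or not mask.any() else mask.astype(np.uint8)
    for z0 in range(0, nrows, _chunk):
        z1 = min(z0 + _chunk, nrows)
        zw = vol.slice_world_z(np.arange(z0, z1))
        pos = np.broadcast_to(inplane, (z1 - z0, ncols, nsteps, 3)).copy()
        pos[..., 2] = zw[:, None, None]
        idxs = (pos - np.asarray(vol.origin)) / np.asarray(vol.spacing)
        np.clip(idxs, 0.0, np.asarray(vol.shape, float) - 1.0, out=idxs)
        pos = idxs * np.asarray(vol.spacing) + np.asarray(vol.origin)
        vals = ndimage.map_coordinates(
            vol.voxels, idxs.reshape(-1, 3).T, order=1, mode="nearest"
        ).reshape(pos.shape[:-1])
        if mask_u8 is not None:
            idx = (pos - np.asarray(vol.origin)) / np.asarray(vol.spacing)
            inmask = ndimage.map_coordinates(mask_u8, idx.reshape(-1, 3).T, order=0,
                                             mode="constant", cval=0)
            vals = np.where(inmask.reshape(vals.shape) > 0, -np.inf, vals)
        arg = vals.argmax(axis=2)
        best = np.take_along_axis(vals, arg[..., None], axis=2)[..., 0]
        best = np.where(np.isfinite(best), best, OUTSIDE_HU)
        pixels[z0:z1] = best.astype(np.float32)
        sample_points[z0:z1] = np.take_along_axis(
            pos, arg[..., None, None], axis=2
        )[..., 0, :]
    attribution = np.full((nrows, ncols), CONTEXT, dtype=np.int16)
    return ReformattedImage(
        pixels=pixels, angle=float(angle), row_spacing=vol.spacing[2],
        col_spacing=cs, labels=[], attribution=attribution,
        sample_points=sample_points,
        meta={"mode": "mip", "bone_suppressed": mask is not None,
              "screen_columns": xs},
    )


# ---------------------------------------------------------------------------
# rotation series
# ---------------------------------------------------------------------------

def render_series(
    vol: Volume,
    tree: CenterlineTree | None,
    mode: str,
    halfwidth_mm: float = DEFAULT_HALFWIDTH_MM,
    bone_mask: np.ndarray | None = None,
    range_deg: float = 180.0,
    step_deg: float = 9.0,
    **kwargs,
) -> list[ReformattedImage]:
    """The fully automated rotation series: one image per 9-degree step.

    Default geometry yields 21 views from -90 (right lateral) through 0
    (anteroposterior) to +90 (left lateral).
    """
    angles = rotation_angles(range_deg, step_deg)
    images = []
    if mode == "mip" and bone_mask is None:
        bone_mask = segment_bones(vol)
    for a in angles:
        if mode == "mpcpr":
            if tree is None:
                raise UsageError("mpcpr series requires a centerline tree")
            img = render_mpcpr(vol, tree, a, halfwidth_mm, **kwargs)
        elif mode == "mip":
            img = render_mip(vol, bone_mask, a, **kwargs)
        else:
            raise UsageError(f"unknown series mode {mode!r}")
        img.meta["series_angle_deg"] = a
        images.append(img)
    return images
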
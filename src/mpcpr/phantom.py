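"""Synthetic peripheral-CTA phantoms with ground-truth centerlines and lesions.

The generator emulates the imaging substrate of a contrast-enhanced
lower-limb CT angiogram: an enhancing arterial tree (lumen at least 150 HU
above soft tissue, mirroring the bolus-trigger enhancement target), soft
tissue background, optional bone rods, wall calcifications, stents,
occlusions, and early-enhancing accompanying veins running parallel to a
named artery.  Every phantom carries its ground truth: per-slice
centerlines, the 21-segment anatomical model per leg, and per-segment worst
stenosis severity with the >70% significance flag.

The anatomical model follows the standard peripheral run-off segmentation:
CIA, EIA, IIA, CFA, DFA, SFA (proximal/middle/distal), POP (x3), ATA (x3),
TPT, PA (x3), PTA (x3) - 21 segments per leg in three groups (iliac,
femoro-popliteal, infra-popliteal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from mpcpr.centerline import CenterlinePath, CenterlineTree, resample_per_slice
from mpcpr.errors import SpecError
from mpcpr.volume import HU_MAX, HU_MIN, Volume

# ---------------------------------------------------------------------------
# Anatomical model: names, groups, path composition
# ---------------------------------------------------------------------------

GROUP_ILIAC = "iliac"
GROUP_FEMPOP = "femoro-popliteal"
GROUP_INFRAPOP = "infra-popliteal"

#: the 21 segment labels of one leg, proximal to distal
LEG_SEGMENTS: tuple[str, ...] = (
    "CIA", "EIA", "IIA", "CFA", "DFA",
    "SFA_prox", "SFA_mid", "SFA_dist",
    "POP_prox", "POP_mid", "POP_dist",
    "ATA_prox", "ATA_mid", "ATA_dist",
    "TPT",
    "PA_prox", "PA_mid", "PA_dist",
    "PTA_prox", "PTA_mid", "PTA_dist",
)

SEGMENT_GROUPS: dict[str, str] = {
    "CIA": GROUP_ILIAC, "EIA": GROUP_ILIAC, "IIA": GROUP_ILIAC,
    "CFA": GROUP_FEMPOP, "DFA": GROUP_FEMPOP,
    "SFA_prox": GROUP_FEMPOP, "SFA_mid": GROUP_FEMPOP, "SFA_dist": GROUP_FEMPOP,
    "POP_prox": GROUP_FEMPOP, "POP_mid": GROUP_FEMPOP, "POP_dist": GROUP_FEMPOP,
    "ATA_prox": GROUP_INFRAPOP, "ATA_mid": GROUP_INFRAPOP, "ATA_dist": GROUP_INFRAPOP,
    "TPT": GROUP_INFRAPOP,
    "PA_prox": GROUP_INFRAPOP, "PA_mid": GROUP_INFRAPOP, "PA_dist": GROUP_INFRAPOP,
    "PTA_prox": GROUP_INFRAPOP, "PTA_mid": GROUP_INFRAPOP, "PTA_dist": GROUP_INFRAPOP,
}

#: root-to-endpoint paths of one leg: path name -> ordered branch names
LEG_PATHS: dict[str, tuple[str, ...]] = {
    "dorsal_pedal": (
        "CIA", "EIA", "CFA", "SFA_prox", "SFA_mid", "SFA_dist",
        "POP_prox", "POP_mid", "POP_dist", "ATA_prox", "ATA_mid", "ATA_dist",
    ),
    "plantar": (
        "CIA", "EIA", "CFA", "SFA_prox", "SFA_mid", "SFA_dist",
        "POP_prox", "POP_mid", "POP_dist", "TPT", "PTA_prox", "PTA_mid", "PTA_dist",
    ),
    "peroneal": (
        "CIA", "EIA", "CFA", "SFA_prox", "SFA_mid", "SFA_dist",
        "POP_prox", "POP_mid", "POP_dist", "TPT", "PA_prox", "PA_mid", "PA_dist",
    ),
    "internal_iliac": ("CIA", "IIA"),
    "deep_femoral": ("CIA", "EIA", "CFA", "DFA"),
}

#: the canonical grading path of each segment (each segment graded exactly once)
SEGMENT_PATH: dict[str, str] = {
    "CIA": "dorsal_pedal", "EIA": "dorsal_pedal", "IIA": "internal_iliac",
    "CFA": "dorsal_pedal", "DFA": "deep_femoral",
    "SFA_prox": "dorsal_pedal", "SFA_mid": "dorsal_pedal", "SFA_dist": "dorsal_pedal",
    "POP_prox": "dorsal_pedal", "POP_mid": "dorsal_pedal", "POP_dist": "dorsal_pedal",
    "ATA_prox": "dorsal_pedal", "ATA_mid": "dorsal_pedal", "ATA_dist": "dorsal_pedal",
    "TPT": "plantar",
    "PTA_prox": "plantar", "PTA_mid": "plantar", "PTA_dist": "plantar",
    "PA_prox": "peroneal", "PA_mid": "peroneal", "PA_dist": "peroneal",
}


@dataclass
class VesselBranch:
    """One named vessel segment: an axis polyline (monotone in z) + radius."""

    name: str
    points: np.ndarray  # (N, 3) world mm
    radius: float  # mm, baseline radius before lesions

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise SpecError(f"branch {self.name!r} needs >= 2 points")
        if np.any(np.diff(self.points[:, 2]) < 0):
            raise SpecError(f"branch {self.name!r} must be monotone in z")
        if self.radius <= 0:
            raise SpecError(f"branch {self.name!r} radius must be > 0")

    def arclength(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Lesion:
    """A focal lesion located by arclength within one named segment.

    ``severity`` is the fractional diameter reduction ``1 - d_min/d_ref``
    for stenoses (strictly inside (0, 1)); occlusions have severity 1.
    """

    kind: str  # stenosis | occlusion | calcification | stent
    segment: str
    start: float  # arclength mm from the segment's proximal end
    length: float  # mm
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("stenosis", "occlusion", "calcification", "stent"):
            raise SpecError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "occlusion":
            self.severity = 1.0
        if self.kind == "stenosis" and not (0.0 < self.severity < 1.0):
            raise SpecError(f"stenosis severity must be in (0,1), got {self.severity}")
        if self.length <= 0 or self.start < 0:
            raise SpecError("lesion needs start >= 0 and length > 0")


@dataclass
class VeinOverlay:
    """An early-enhancing accompanying vein parallel to a named artery."""

    artery: str  # branch name or artery prefix, e.g. "L_PTA"
    offset: tuple[float, float] = (3.0, 0.0)  # in-plane (x, y) offset, mm
    radius: float | None = None  # default: same as the artery


@dataclass
class SegmentDef:
    """One graded anatomical segment: half-open world-z extent on one path."""

    name: str  # full label, e.g. "L_SFA_mid"
    group: str
    path: str  # full path name, e.g. "L_dorsal_pedal"
    z_lo: float
    z_hi: float  # half-open [z_lo, z_hi)


# ---------------------------------------------------------------------------
# Default tree geometry
# ---------------------------------------------------------------------------

# z fractions of the usable volume extent, proximal -> distal
_ZF = {
    "aorta": (0.02, 0.06),
    "CIA": (0.06, 0.13),
    "EIA": (0.13, 0.20),
    "IIA": (0.13, 0.18),
    "CFA": (0.20, 0.26),
    "DFA": (0.26, 0.36),
    "SFA": (0.26, 0.50),
    "POP": (0.50, 0.64),
    "ATA": (0.64, 0.97),
    "TPT": (0.64, 0.70),
    "PA": (0.70, 0.97),
    "PTA": (0.70, 0.97),
}

#: baseline radii (mm), plausible adult lower-limb calibres
_RADII = {
    "aorta": 5.0, "CIA": 4.0, "EIA": 3.5, "IIA": 2.5, "CFA": 3.5, "DFA": 2.5,
    "SFA": 3.0, "POP": 2.5, "ATA": 1.5, "TPT": 2.0, "PA": 1.5, "PTA": 1.5,
}


def _thirds(p0: np.ndarray, p1: np.ndarray, stem: str, radius: float) -> list[VesselBranch]:
    """Split a straight artery into proximal/middle/distal equal-arclength thirds."""
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    cut1, cut2 = a + (b - a) / 3.0, a + 2.0 * (b - a) / 3.0
    return [
        VesselBranch(f"{stem}_prox", np.stack([a, cut1]), radius),
        VesselBranch(f"{stem}_mid", np.stack([cut1, cut2]), radius),
        VesselBranch(f"{stem}_dist", np.stack([cut2, b]), radius),
    ]


def default_leg_tree(
    side: str,
    shape: tuple[int, int, int] = (96, 96, 120),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> list[VesselBranch]:
    """The default 21-segment arterial tree of one leg.

    ``side`` is "left" or "right"; the two trees are mirror images in x
    about the volume centre.  Branch endpoints are shared exactly so that
    consecutive segments chain into continuous root-to-endpoint paths.
    """
    if side not in ("left", "right"):
        raise SpecError(f"side must be 'left' or 'right', got {side!r}")
    sgn = 1.0 if side == "left" else -1.0
    ext = np.asarray(shape, float) * np.asarray(spacing, float)
    xc = origin[0] + ext[0] / 2.0
    yc = origin[1] + ext[1] / 2.0
    z0, z1 = origin[2], origin[2] + ext[2]
    x_leg = 0.22 * ext[0]

    def zf(f: float) -> float:
        return z0 + f * (z1 - z0)

    def P(x, y, f):
        return np.array([x, y, zf(f)])

    br: list[VesselBranch] = []
    x_cia = xc + sgn * 0.5 * x_leg
    x_fem = xc + sgn * x_leg
    br.append(VesselBranch("CIA", np.stack([P(xc, yc, _ZF["CIA"][0]), P(x_cia, yc, _ZF["CIA"][1])]), _RADII["CIA"]))
    br.append(VesselBranch("EIA", np.stack([P(x_cia, yc, _ZF["EIA"][0]), P(x_fem, yc, _ZF["EIA"][1])]), _RADII["EIA"]))
    br.append(VesselBranch("IIA", np.stack([P(x_cia, yc, _ZF["IIA"][0]), P(x_cia - sgn * 6.0, yc + 4.0, _ZF["IIA"][1])]), _RADII["IIA"]))
    br.append(VesselBranch("CFA", np.stack([P(x_fem, yc, _ZF["CFA"][0]), P(x_fem, yc, _ZF["CFA"][1])]), _RADII["CFA"]))
    br.append(VesselBranch("DFA", np.stack([P(x_fem, yc, _ZF["DFA"][0]), P(x_fem, yc + 7.0, _ZF["DFA"][1])]), _RADII["DFA"]))
    br.extend(_thirds(P(x_fem, yc, _ZF["SFA"][0]), P(x_fem, yc, _ZF["SFA"][1]), "SFA", _RADII["SFA"]))
    br.extend(_thirds(P(x_fem, yc, _ZF["POP"][0]), P(x_fem, yc, _ZF["POP"][1]), "POP", _RADII["POP"]))
    # infra-popliteal run-off: ATA deviates laterally+anteriorly over its
    # proximal third, PA posteriorly, PTA medially
    f0, f1 = _ZF["ATA"]
    fa = f0 + (f1 - f0) / 3.0
    ata0, ata1 = P(x_fem, yc, f0), P(x_fem + sgn * 5.0, yc - 5.0, fa)
    ata2 = np.array([ata1[0], ata1[1], zf(f0 + 2 * (f1 - f0) / 3.0)])
    ata3 = np.array([ata1[0], ata1[1], zf(f1)])
    br.append(VesselBranch("ATA_prox", np.stack([ata0, ata1]), _RADII["ATA"]))
    br.append(VesselBranch("ATA_mid", np.stack([ata1, ata2]), _RADII["ATA"]))
    br.append(VesselBranch("ATA_dist", np.stack([ata2, ata3]), _RADII["ATA"]))
    br.append(VesselBranch("TPT", np.stack([P(x_fem, yc, _ZF["TPT"][0]), P(x_fem, yc, _ZF["TPT"][1])]), _RADII["TPT"]))
    f0, f1 = _ZF["PA"]
    fa = f0 + (f1 - f0) / 3.0
    pa0, pa1 = P(x_fem, yc, f0), P(x_fem, yc + 5.0, fa)
    pa2 = np.array([pa1[0], pa1[1], zf(f0 + 2 * (f1 - f0) / 3.0)])
    pa3 = np.array([pa1[0], pa1[1], zf(f1)])
    br.append(VesselBranch("PA_prox", np.stack([pa0, pa1]), _RADII["PA"]))
    br.append(VesselBranch("PA_mid", np.stack([pa1, pa2]), _RADII["PA"]))
    br.append(VesselBranch("PA_dist", np.stack([pa2, pa3]), _RADII["PA"]))
    f0, f1 = _ZF["PTA"]
    fa = f0 + (f1 - f0) / 3.0
    pt0, pt1 = P(x_fem, yc, f0), P(x_fem - sgn * 5.0, yc, fa)
    pt2 = np.array([pt1[0], pt1[1], zf(f0 + 2 * (f1 - f0) / 3.0)])
    pt3 = np.array([pt1[0], pt1[1], zf(f1)])
    br.append(VesselBranch("PTA_prox", np.stack([pt0, pt1]), _RADII["PTA"]))
    br.append(VesselBranch("PTA_mid", np.stack([pt1, pt2]), _RADII["PTA"]))
    br.append(VesselBranch("PTA_dist", np.stack([pt2, pt3]), _RADII["PTA"]))
    return br


@dataclass
class TreeModel:
    """Default two-leg geometry bundle: branches, aorta stub, paths, segments."""

    branches: dict[str, VesselBranch]  # keys with L_/R_ prefix
    aorta: VesselBranch
    paths: dict[str, tuple[str, ...]]  # path name -> ordered branch names
    segments: list[SegmentDef]
    root: np.ndarray  # infra-renal aortic seed point

    def path_polyline(self, path_name: str) -> np.ndarray:
        """Concatenated axis polyline of one root-to-endpoint path."""
        pts = [self.aorta.points]
        for bname in self.paths[path_name]:
            bp = self.branches[bname].points
            pts.append(bp[1:] if np.allclose(bp[0], pts[-1][-1]) else bp)
        return np.vstack(pts)

    def truth_tree(self, spacing_z: float, origin_z: float) -> CenterlineTree:
        tree = CenterlineTree(root=self.root)
        for pname in self.paths:
            tree.paths[pname] = resample_per_slice(
                self.path_polyline(pname), origin_z, spacing_z, name=pname
            )
        return tree


def default_tree_model(
    shape: tuple[int, int, int] = (96, 96, 120),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TreeModel:
    """Two mirrored legs plus a shared infra-renal aortic stub."""
    ext = np.asarray(shape, float) * np.asarray(spacing, float)
    xc = origin[0] + ext[0] / 2.0
    yc = origin[1] + ext[1] / 2.0
    z0, z1 = origin[2], origin[2] + ext[2]
    aorta = VesselBranch(
        "AORTA",
        np.stack([
            [xc, yc, z0 + _ZF["aorta"][0] * (z1 - z0)],
            [xc, yc, z0 + _ZF["aorta"][1] * (z1 - z0)],
        ]),
        _RADII["aorta"],
    )
    branches: dict[str, VesselBranch] = {}
    paths: dict[str, tuple[str, ...]] = {}
    segments: list[SegmentDef] = []
    for side, pre in (("left", "L_"), ("right", "R_")):
        for b in default_leg_tree(side, shape, spacing, origin):
            branches[pre + b.name] = replace(b, name=pre + b.name)
        for pname, bnames in LEG_PATHS.items():
            paths[pre + pname] = tuple(pre + b for b in bnames)
        for seg in LEG_SEGMENTS:
            b = branches[pre + seg]
            segments.append(
                SegmentDef(
                    name=pre + seg,
                    group=SEGMENT_GROUPS[seg],
                    path=pre + SEGMENT_PATH[seg],
                    z_lo=float(b.points[0, 2]),
                    z_hi=float(b.points[-1, 2]),
                )
            )
    return TreeModel(branches=branches, aorta=aorta, paths=paths,
                     segments=segments, root=aorta.points[0].copy())


# ---------------------------------------------------------------------------
# PhantomSpec and ground truth
# ---------------------------------------------------------------------------

SIGNIFICANCE_THRESHOLD = 0.70  # fractional diameter reduction; strict >


@dataclass
class PhantomSpec:
    """Full description of a synthetic peripheral-CTA volume.

    The default HU palette (soft tissue 40, lumen 400, bone 1000,
    calcification 800, stent 2000, vein 300) models an 80-kV CTA with the
    arterial enhancement comfortably above the 150-HU bolus-trigger floor;
    every level is overridable.
    """

    shape: tuple[int, int, int] = (96, 96, 120)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = 40.0
    lumen_hu: float = 400.0
    bone_hu: float = 1000.0
    calcification_hu: float = 800.0
    stent_hu: float = 2000.0
    vein_hu: float = 300.0
    noise_sd: float = 10.0
    tree: TreeModel | None = None  # None -> default two-leg model for shape
    lesions: list[Lesion] = field(default_factory=list)
    vein_overlay: VeinOverlay | None = None
    bones: list[VesselBranch] = field(default_factory=list)
    seed: int = 0

    def resolved_tree(self) -> TreeModel:
        return self.tree if self.tree is not None else default_tree_model(
            self.shape, self.spacing, self.origin
        )

    def validate(self, model: TreeModel) -> None:
        if self.lumen_hu - self.background_hu < 150.0:
            raise SpecError(
                "lumen_hu must exceed background_hu by >= 150 HU "
                f"(got {self.lumen_hu - self.background_hu:g})"
            )
        for v in (self.background_hu, self.lumen_hu, self.bone_hu,
                  self.calcification_hu, self.stent_hu, self.vein_hu):
            if not (HU_MIN <= v <= HU_MAX):
                raise SpecError(f"HU level {v:g} outside [{HU_MIN:g}, {HU_MAX:g}]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for les in self.lesions:
            if les.segment not in model.branches:
                raise SpecError(
                    f"lesion references unknown segment {les.segment!r}; "
                    f"known: {sorted(model.branches)}"
                )
            L = model.branches[les.segment].arclength()
            if les.start + les.length > L + 1e-6:
                raise SpecError(
                    f"lesion extent [{les.start}, {les.start + les.length}] mm "
                    f"exceeds segment {les.segment!r} length {L:.1f} mm"
                )
        if self.vein_overlay is not None:
            pre = self.vein_overlay.artery
            if not any(n == pre or n.startswith(pre + "_") for n in model.branches):
                raise SpecError(f"vein overlay references unknown artery {pre!r}")


@dataclass
class GroundTruth:
    """Everything a downstream test needs to score itself against."""

    centerlines: CenterlineTree
    worst_stenosis: dict[str, float]  # segment label -> worst fraction in [0,1]
    significant: dict[str, bool]  # worst fraction > 0.70 (strict)
    lesions: list[Lesion]
    segment_model: list[SegmentDef]
    lumen_mask: np.ndarray  # arterial lumen, coverage >= 0.5
    bone_mask: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "centerlines": self.centerlines.to_dict(),
            "worst_stenosis": self.worst_stenosis,
            "significant": self.significant,
            "lesions": [vars(l) for l in self.lesions],
            "segments": [vars(s) for s in self.segment_model],
        }


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _densify(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~``step`` mm; returns (samples, arclengths)."""
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    n = max(int(np.ceil(total / step)) + 1, 2)
    s_nodes = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(s, s_nodes, points[:, d])
    return out, s


class _Painter:
    """Accumulates antialiased tube/shell rasterizations into a voxel grid."""

    def __init__(self, shape, spacing, origin):
        self.shape = np.asarray(shape, int)
        self.spacing = np.asarray(spacing, float)
        self.origin = np.asarray(origin, float)
        self.vox: np.ndarray | None = None
        self.aa = float(self.spacing[:2].min())  # antialias width ~ in-plane voxel

    def _bbox(self, pts: np.ndarray, pad: float):
        lo = np.floor((pts.min(0) - pad - self.origin) / self.spacing).astype(int)
        hi = np.ceil((pts.max(0) + pad - self.origin) / self.spacing).astype(int) + 1
        lo = np.clip(lo, 0, self.shape)
        hi = np.clip(hi, 0, self.shape)
        if np.any(hi <= lo):
            return None
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    def _grid_world(self, sl) -> np.ndarray:
        axes = [
            self.origin[d] + np.arange(sl[d].start, sl[d].stop) * self.spacing[d]
            for d in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def paint_tube(self, points, radii, value, coverage_out=None):
        """Blend a (possibly tapering) tube of ``value`` HU into the grid."""
        pts, s = _densify(points, 0.25 * float(self.spacing.min()))
        if np.isscalar(radii):
            r = np.full(len(pts), float(radii))
        else:
            # radii given per arclength via callable
            r = np.asarray(radii(s), dtype=float)
        rmax = float(r.max(initial=0.0))
        if rmax <= 0:
            return
        sl = self._bbox(pts, rmax + 2 * self.aa)
        if sl is None:
            return
        world = self._grid_world(sl)
        d, idx = cKDTree(pts).query(world, workers=-1)
        rn = r[idx]
        cov = np.clip((rn - d) / self.aa + 0.5, 0.0, 1.0)
        # sub-voxel tubes cover at most their cross-section's share of the
        # voxel; in particular an occluded extent (r = 0) paints nothing
        cov *= np.clip(np.pi * rn * rn / (self.aa * self.aa), 0.0, 1.0)
        self._blend(sl, cov, value, coverage_out)

    def paint_shell(self, points, r_inner, thickness, value, half_plane=False,
                    coverage_out=None):
        """A cylindrical shell [r_inner, r_inner+thickness] around the axis.

        With ``half_plane`` only the half-space on one fixed side of the
        axis is painted (a calcified crescent on the vessel wall).
        """
        pts, s = _densify(points, 0.25 * float(self.spacing.min()))
        if np.isscalar(r_inner):
            ri = np.full(len(pts), float(r_inner))
        else:
            ri = np.asarray(r_inner(s), dtype=float)
        ro = ri + thickness
        sl = self._bbox(pts, float(ro.max()) + 2 * self.aa)
        if sl is None:
            return
        world = self._grid_world(sl)
        d, idx = cKDTree(pts).query(world, workers=-1)
        cov = np.clip((ro[idx] - d) / self.aa + 0.5, 0, 1) * np.clip(
            (d - ri[idx]) / self.aa + 0.5, 0, 1
        )
        if half_plane:
            # fixed crescent side: the in-plane direction most aligned with +x
            tang = np.gradient(pts, axis=0)
            tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
            xhat = np.array([1.0, 0.0, 0.0])
            n = xhat - tang * (tang @ xhat)[:, None]
            bad = np.linalg.norm(n, axis=1) < 1e-6
            n[bad] = [0.0, 1.0, 0.0]
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            side = np.einsum("ij,ij->i", world - pts[idx], n[idx])
            cov = cov * (side > 0)
        self._blend(sl, cov, value, coverage_out)

    def _blend(self, sl, cov, value, coverage_out):
        region = self.vox[sl]
        cov = cov.reshape(region.shape)
        region *= 1.0 - cov
        region += value * cov
        if coverage_out is not None:
            np.maximum(coverage_out[sl], cov, out=coverage_out[sl])


def _radius_profile(branch: VesselBranch, lesions: Sequence[Lesion]):
    """Return a callable r(s) applying stenosis tapers / occlusions to a branch.

    The stenosis taper is a raised-cosine dip: the radius reaches
    ``(1 - severity) * r0`` exactly at the lesion centre and returns
    smoothly to ``r0`` at both ends.
    """
    r0 = branch.radius
    mine = [l for l in lesions if l.segment == branch.name and l.kind in ("stenosis", "occlusion")]

    def r(s: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(s, float), r0)
        for les in mine:
            inside = (s >= les.start) & (s <= les.start + les.length)
            if les.kind == "occlusion":
                out[inside] = 0.0
            else:
                w = 0.5 * (1.0 - np.cos(2.0 * np.pi * (s[inside] - les.start) / les.length))
                out[inside] = np.minimum(out[inside], r0 * (1.0 - les.severity * w))
        return out

    return r


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Rasterize a phantom volume and its ground truth.

    Painting order (later wins where structures overlap): soft tissue,
    bone, veins, arterial lumen, calcification crescents, stent shells;
    then Gaussian noise and the HU-range clip.  Identical spec + seed give
    voxel-identical volumes.
    """
    model = spec.resolved_tree()
    spec.validate(model)
    painter = _Painter(spec.shape, spec.spacing, spec.origin)
    painter.vox = np.full(tuple(spec.shape), float(spec.background_hu), dtype=np.float64)
    lumen_cov = np.zeros(tuple(spec.shape), dtype=np.float32)
    bone_cov = np.zeros(tuple(spec.shape), dtype=np.float32) if spec.bones else None

    for rod in spec.bones:
        painter.paint_tube(rod.points, rod.radius, spec.bone_hu, coverage_out=bone_cov)

    if spec.vein_overlay is not None:
        ov = spec.vein_overlay
        off = np.array([ov.offset[0], ov.offset[1], 0.0])
        for name, b in model.branches.items():
            if name == ov.artery or name.startswith(ov.artery + "_"):
                painter.paint_tube(b.points + off, ov.radius or b.radius, spec.vein_hu)

    # arterial lumen (aorta + every branch), lesion-modified radii
    painter.paint_tube(model.aorta.points, model.aorta.radius, spec.lumen_hu,
                       coverage_out=lumen_cov)
    for b in model.branches.values():
        painter.paint_tube(b.points, _radius_profile(b, spec.lesions), spec.lumen_hu,
                           coverage_out=lumen_cov)

    for les in spec.lesions:
        b = model.branches[les.segment]
        pts, _ = _densify(b.points, 0.25 * min(spec.spacing))
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        sel = (s >= les.start) & (s <= les.start + les.length)
        if sel.sum() < 2:
            continue
        sub = pts[sel]
        if les.kind == "calcification":
            rprof = _radius_profile(b, spec.lesions)
            s0 = float(s[sel][0])
            painter.paint_shell(sub, lambda q, s0=s0, rp=rprof: rp(np.asarray(q) + s0),
                                1.5, spec.calcification_hu, half_plane=True)
        elif les.kind == "stent":
            painter.paint_shell(sub, b.radius, 1.0, spec.stent_hu)

    np.clip(painter.vox, HU_MIN, HU_MAX, out=painter.vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        painter.vox += rng.normal(0.0, spec.noise_sd, size=painter.vox.shape)
        np.clip(painter.vox, HU_MIN, HU_MAX, out=painter.vox)

    vol = Volume(painter.vox.astype(np.float32), spec.spacing, spec.origin)

    worst = {name: 0.0 for name in model.branches}
    for les in spec.lesions:
        if les.kind == "stenosis":
            worst[les.segment] = max(worst[les.segment], les.severity)
        elif les.kind == "occlusion":
            worst[les.segment] = 1.0
    truth = GroundTruth(
        centerlines=model.truth_tree(spec.spacing[2], spec.origin[2]),
        worst_stenosis=worst,
        significant={k: v > SIGNIFICANCE_THRESHOLD for k, v in worst.items()},
        lesions=list(spec.lesions),
        segment_model=model.segments,
        lumen_mask=lumen_cov >= 0.5,
        bone_mask=None if bone_cov is None else bone_cov >= 0.5,
    )
    return vol, truth


def smooth_cylinder_volume(
    shape: tuple[int, int, int] = (128, 128, 160),
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    background_hu: float = 40.0,
    amplitude_hu: float = 200.0,
    sigma_mm: float = 6.0,
) -> tuple[Volume, np.ndarray]:
    """A z-invariant cylinder with a Gaussian radial enhancement profile.

    Unlike the hard-edged tubes of :func:`generate_phantom`, this field is
    band-limited, so trilinear resampling reproduces it to a fraction of an
    HU at any in-plane rotation.  It is the probe of choice for checking
    that a renderer introduces no angle-dependent artifact beyond
    interpolation: on a rasterized *sharp* edge, lattice aliasing alone
    contributes tens of HU and would mask any renderer defect.

    Returns the volume and the axis polyline (one point per slice).
    """
    nx, ny, nz = shape
    x = (np.arange(nx) * spacing[0])[:, None]
    y = (np.arange(ny) * spacing[1])[None, :]
    xc = (nx - 1) * spacing[0] / 2.0
    yc = (ny - 1) * spacing[1] / 2.0
    r2 = (x - xc) ** 2 + (y - yc) ** 2
    plane = background_hu + amplitude_hu * np.exp(-r2 / (2.0 * sigma_mm ** 2))
    vox = np.repeat(plane[:, :, None], nz, axis=2).astype(np.float32)
    axis = np.stack(
        [np.full(nz, xc), np.full(nz, yc), np.arange(nz) * spacing[2]], axis=1
    )
    return Volume(vox, spacing), axis


def straight_tube_spec(
    radius: float = 4.0,
    shape: tuple[int, int, int] = (48, 48, 80),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    lesions: Sequence[Lesion] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    **hu_overrides,
) -> PhantomSpec:
    """A single straight z-aligned tube on the volume axis (test workhorse).

    The tube is registered as segment ``"TUBE"`` on path ``"tube"`` so the
    full lesion / grading machinery applies to it.
    """
    ext = np.asarray(shape, float) * np.asarray(spacing, float)
    xc, yc = ext[0] / 2.0, ext[1] / 2.0
    z_lo, z_hi = 0.05 * ext[2], 0.95 * ext[2]
    tube = VesselBranch("TUBE", np.array([[xc, yc, z_lo], [xc, yc, z_hi]]), radius)
    stub = VesselBranch("ROOT", np.array([[xc, yc, 0.02 * ext[2]], [xc, yc, z_lo]]), radius)
    model = TreeModel(
        branches={"TUBE": tube},
        aorta=stub,
        paths={"tube": ("TUBE",)},
        segments=[SegmentDef("TUBE", GROUP_FEMPOP, "tube", z_lo, z_hi)],
        root=stub.points[0].copy(),
    )
    return PhantomSpec(
        shape=shape, spacing=spacing, tree=model,
        lesions=list(lesions or []), noise_sd=noise_sd, seed=seed, **hu_overrides,
    )
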
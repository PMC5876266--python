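"""Lumen caliber profiling and per-segment stenosis grading.

The graded quantity is the fractional diameter reduction of the worst
lesion in a segment, ``100 * (1 - d_min / d_ref)`` percent, judged against
the hemodynamic-significance rule: significant iff the percentage strictly
exceeds 70.  Because human readers grade visually, the reference diameter
needs an explicit quantitative rule here: ``d_ref`` is the median
effective diameter over the segment's assessable slices after discarding
the narrowest 20% (robust against the lesion itself biasing its own
reference).  Occluded segments grade 100% and significant; segments whose
whole extent is unassessable receive a non-assessable verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from mpcpr.centerline import CenterlinePath, CenterlineTree
from mpcpr.errors import MappingError, UsageError
from mpcpr.phantom import SegmentDef
from mpcpr.tracking import _plane_basis, _sample_plane
from mpcpr.volume import Volume

VERDICT_SIGNIFICANT = "significant"
VERDICT_NON_SIGNIFICANT = "non_significant"
NA_VERDICTS = (
    "na_not_depicted",
    "na_low_contrast",
    "na_calcified",
    "na_prosthesis",
    "na_stent",
)
SIGNIFICANT_PERCENT = 70.0  # strict: exactly 70% is NOT significant


def is_na(verdict: str) -> bool:
    return verdict.startswith("na_")


@dataclass
class LumenProfile:
    """Per-slice lumen caliber along one centerline path."""

    path: str
    slice_indices: np.ndarray  # (N,)
    arclength: np.ndarray  # (N,) mm, strictly increasing
    area: np.ndarray  # (N,) mm^2
    assessable: np.ndarray  # (N,) bool

    @property
    def diameter(self) -> np.ndarray:
        """Effective circular diameter, 2*sqrt(area/pi) (mm)."""
        return 2.0 * np.sqrt(self.area / np.pi)

    def select(self, s_lo: float, s_hi: float) -> np.ndarray:
        """Indices of slices with arclength in the half-open [s_lo, s_hi)."""
        return np.nonzero((self.arclength >= s_lo) & (self.arclength < s_hi))[0]


@dataclass
class SegmentRating:
    """The per-segment verdict a reader (or this module) produces."""

    segment: str
    group: str
    verdict: str
    worst_percent: float  # NaN when non-assessable


def lumen_profile(
    vol: Volume,
    path: CenterlinePath,
    lumen_threshold: float,
    search_radius_mm: float = 10.0,
) -> LumenProfile:
    """Cross-sectional lumen area per slice along a resampled path.

    The area is the above-threshold region connected to the centerline
    point in the plane orthogonal to the local tangent, measured by
    sub-voxel plane resampling.  Slices whose centerline point lies below
    the threshold are unassessable with area 0.
    """
    if not path.resampled:
        raise UsageError("lumen_profile requires a resampled path")
    step = 0.5 * min(vol.spacing[0], vol.spacing[1])
    tangents = np.gradient(path.points, axis=0)
    n = len(path.points)
    area = np.zeros(n)
    assessable = np.zeros(n, dtype=bool)
    for i in range(n):
        e1, e2 = _plane_basis(tangents[i])
        vals, o1, o2 = _sample_plane(vol, path.points[i], e1, e2,
                                     search_radius_mm, step)
        mask = vals >= lumen_threshold
        ci = o1.shape[0] // 2
        if not mask[ci, ci]:
            continue
        lab = cc_label(mask, connectivity=2)
        comp = lab == lab[ci, ci]
        area[i] = comp.sum() * step * step
        assessable[i] = True
    return LumenProfile(
        path=path.name,
        slice_indices=np.asarray(path.slice_indices).copy(),
        arclength=path.arclength(),
        area=area,
        assessable=assessable,
    )


def stenosis_percent(d_min: float, d_ref: float) -> float:
    """Fractional diameter reduction as a percentage, clipped to [0, 100]."""
    if d_ref <= 0:
        return 100.0
    return float(np.clip(100.0 * (1.0 - d_min / d_ref), 0.0, 100.0))


def reference_diameter(diameters: np.ndarray, exclude_worst_frac: float = 0.2) -> float:
    """Median diameter after discarding the narrowest ``exclude_worst_frac``."""
    d = np.sort(np.asarray(diameters, float))
    k = int(np.floor(exclude_worst_frac * len(d)))
    kept = d[k:] if k < len(d) else d
    return float(np.median(kept))


def grade_segment(
    profile: LumenProfile,
    extent: tuple[float, float],
    segment: str = "",
    group: str = "",
) -> SegmentRating:
    """Grade the worst stenosis inside a half-open arclength extent.

    Verdict is ``significant`` iff the worst percentage strictly exceeds
    70; an extent with no assessable slice is rated ``na_low_contrast``
    (callers may override the category from other evidence).
    """
    s_lo, s_hi = extent
    idx = profile.select(s_lo, s_hi)
    if len(idx) == 0:
        raise UsageError(
            f"extent [{s_lo}, {s_hi}) mm contains no profile slice "
            f"(path spans [0, {profile.arclength[-1]:.1f}) mm)"
        )
    assess = profile.assessable[idx]
    if not assess.any():
        return SegmentRating(segment=segment, group=group,
                             verdict="na_low_contrast", worst_percent=float("nan"))
    diam = profile.diameter[idx]
    d_ref = reference_diameter(diam[assess])
    d_min = float(diam.min())  # unassessable slices carry area 0 -> occlusion
    pct = stenosis_percent(d_min, d_ref)
    verdict = VERDICT_SIGNIFICANT if pct > SIGNIFICANT_PERCENT else VERDICT_NON_SIGNIFICANT
    return SegmentRating(segment=segment, group=group, verdict=verdict,
                         worst_percent=pct)


def map_segments(
    tree: CenterlineTree,
    model: Sequence[SegmentDef],
) -> dict[str, tuple[str, tuple[float, float]]]:
    """Map each modelled segment onto a half-open arclength interval.

    Each segment's world-z extent is located on its canonical grading path
    and converted to the path's own arclength parameterisation; intervals
    of consecutive segments on the same path share boundaries exactly, so
    sub-segments partition their parent artery's extent.
    """
    out: dict[str, tuple[str, tuple[float, float]]] = {}
    for seg in model:
        if seg.path not in tree.paths:
            artery = seg.name
            raise MappingError(
                f"tree has no path {seg.path!r} needed to grade {artery!r}; "
                f"available endpoints: {sorted(tree.paths)}"
            )
        path = tree.paths[seg.path]
        if not path.resampled:
            raise UsageError(f"path {seg.path!r} must be resampled")
        s = path.arclength()
        z = path.points[:, 2]
        inside = (z >= seg.z_lo - 1e-9) & (z < seg.z_hi - 1e-9)
        if not inside.any():
            raise MappingError(
                f"segment {seg.name!r} z-extent [{seg.z_lo:.1f}, {seg.z_hi:.1f}) mm "
                f"is not covered by path {seg.path!r}"
            )
        i0 = int(np.argmax(inside))
        i1 = int(len(inside) - np.argmax(inside[::-1]))  # one past last inside
        s_lo = float(s[i0])
        s_hi = float(s[i1]) if i1 < len(s) else float(s[-1] + 1e-6)
        out[seg.name] = (seg.path, (s_lo, s_hi))
    return out


def grade_tree(
    vol: Volume,
    tree: CenterlineTree,
    model: Sequence[SegmentDef],
    lumen_threshold: float,
) -> list[SegmentRating]:
    """Profile every needed path once and grade all modelled segments."""
    mapping = map_segments(tree, model)
    needed = {p for p, _ in mapping.values()}
    profiles = {
        p: lumen_profile(vol, tree.paths[p], lumen_threshold) for p in sorted(needed)
    }
    groups = {seg.name: seg.group for seg in model}
    ratings = []
    for seg in model:
        pname, extent = mapping[seg.name]
        ratings.append(
            grade_segment(profiles[pname], extent, segment=seg.name,
                          group=groups[seg.name])
        )
    return ratings


def ratings_to_records(ratings: Sequence[SegmentRating],
                       patient: str = "", leg: str = "") -> list[dict]:
    """Flatten ratings for CSV export (patient, leg, segment, group, ...)."""
    return [
        {
            "patient": patient,
            "leg": leg or (r.segment.split("_", 1)[0] if "_" in r.segment else ""),
            "segment": r.segment,
            "group": r.group,
            "verdict": r.verdict,
            "worst_percent": r.worst_percent,
        }
        for r in ratings
    ]
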
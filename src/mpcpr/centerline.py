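"""Centerline containers shared by the phantom, tracking and render modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mpcpr.errors import UsageError
from mpcpr.volume import as_points


@dataclass
class CenterlinePath:
    """An ordered polyline from the tree root to one endpoint.

    When ``resampled`` is true the path holds exactly one point per axial
    slice, with ``slice_indices`` giving the slice index of each point
    (strictly increasing by one).  ``flagged`` marks points where the lumen
    cross-section was empty (e.g. inside an occlusion) and the point could
    not be recentred.
    """

    name: str
    points: np.ndarray  # (N, 3) world mm
    resampled: bool = False
    slice_indices: np.ndarray | None = None  # (N,) int, only when resampled
    flagged: np.ndarray | None = None  # (N,) bool

    def __post_init__(self) -> None:
        self.points = as_points(self.points)
        if len(self.points) < 2:
            raise UsageError(f"path {self.name!r} needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise UsageError(f"path {self.name!r} contains non-finite coordinates")
        if self.resampled:
            if self.slice_indices is None:
                raise UsageError("resampled paths must carry slice_indices")
            self.slice_indices = np.asarray(self.slice_indices, dtype=int)
            if np.any(np.diff(self.slice_indices) != 1):
                raise UsageError(
                    f"resampled path {self.name!r} must advance one slice per point"
                )
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return len(self.points)

    def arclength(self) -> np.ndarray:
        """Cumulative arclength (mm) at each point, starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def point_at_slice(self, k: int) -> np.ndarray | None:
        if self.slice_indices is None:
            return None
        pos = k - int(self.slice_indices[0])
        if 0 <= pos < len(self.points):
            return self.points[pos]
        return None


def resample_per_slice(
    points: np.ndarray,
    origin_z: float,
    spacing_z: float,
    name: str = "path",
    flagged: np.ndarray | None = None,
) -> CenterlinePath:
    """Resample a polyline to one point per axial slice (first z-crossing).

    Vessels that locally reverse z are z-monotonised by taking the first
    crossing of each slice plane.  ``flagged`` markers, if given per input
    point, are carried over to the nearest output point.
    """
    pts = as_points(points)
    z = pts[:, 2]
    k_lo = int(np.ceil(round((z.min() - origin_z) / spacing_z, 9)))
    k_hi = int(np.floor(round((z.max() - origin_z) / spacing_z, 9)))
    if k_hi <= k_lo:
        raise UsageError(f"path {name!r} spans fewer than two slices")
    out = np.empty((k_hi - k_lo + 1, 3))
    out_flags = np.zeros(k_hi - k_lo + 1, dtype=bool)
    src = np.zeros(k_hi - k_lo + 1, dtype=int)
    for row, k in enumerate(range(k_lo, k_hi + 1)):
        zk = origin_z + k * spacing_z
        # first segment crossing the slice plane
        hit = None
        for i in range(len(pts) - 1):
            z0, z1 = z[i], z[i + 1]
            if (z0 - zk) * (z1 - zk) <= 0 and z0 != z1:
                t = (zk - z0) / (z1 - z0)
                hit = pts[i] + t * (pts[i + 1] - pts[i])
                src[row] = i if t < 0.5 else i + 1
                break
            if z0 == zk and z1 == zk:
                hit = pts[i]
                src[row] = i
                break
        if hit is None:  # zk equals an isolated vertex
            j = int(np.argmin(np.abs(z - zk)))
            hit = pts[j].copy()
            hit[2] = zk
            src[row] = j
        out[row] = hit
        out[row, 2] = zk
    if flagged is not None:
        flagged = np.asarray(flagged, dtype=bool)
        out_flags = flagged[src]
    return CenterlinePath(
        name=name,
        points=out,
        resampled=True,
        slice_indices=np.arange(k_lo, k_hi + 1),
        flagged=out_flags,
    )


@dataclass
class CenterlineTree:
    """Root-to-endpoint centerline paths sharing a common trunk.

    ``root`` is the common seed (clinically, a point in the infra-renal
    aorta); each path runs from the root to one named endpoint.
    """

    root: np.ndarray
    paths: dict[str, CenterlinePath] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.root = np.asarray(self.root, dtype=float).reshape(3)

    @property
    def endpoints(self) -> list[str]:
        return list(self.paths)

    def __iter__(self):
        return iter(self.paths.values())

    def __getitem__(self, name: str) -> CenterlinePath:
        return self.paths[name]

    def shared_prefix_length(self, name_a: str, name_b: str, tol: float = 1e-6) -> int:
        """Number of leading points shared (within ``tol``) by two paths."""
        a, b = self.paths[name_a].points, self.paths[name_b].points
        n = min(len(a), len(b))
        same = np.all(np.abs(a[:n] - b[:n]) <= tol, axis=1)
        if same.all():
            return n
        return int(np.argmin(same))

    def to_dict(self) -> dict:
        return {
            "root": self.root.tolist(),
            "paths": {
                name: {
                    "points": p.points.tolist(),
                    "resampled": bool(p.resampled),
                    "slice_indices": None
                    if p.slice_indices is None
                    else p.slice_indices.tolist(),
                    "flagged": None if p.flagged is None else p.flagged.tolist(),
                }
                for name, p in self.paths.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlineTree":
        tree = cls(root=np.asarray(d["root"], dtype=float))
        for name, pd in d["paths"].items():
            tree.paths[name] = CenterlinePath(
                name=name,
                points=np.asarray(pd["points"], dtype=float),
                resampled=bool(pd.get("resampled", False)),
                slice_indices=None
                if pd.get("slice_indices") is None
                else np.asarray(pd["slice_indices"], dtype=int),
                flagged=None
                if pd.get("flagged") is None
                else np.asarray(pd["flagged"], dtype=bool),
            )
        return tree
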
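"""Volume container, coordinate conventions, and NIfTI / DICOM / PNG I/O.

Conventions
-----------
* Voxel indices are 0-based; axis order is ``(x, y, z)`` with axis 2 the
  cranio-caudal slice axis.  Reformations produce one output row per slice.
* World coordinates are axis-aligned: ``world = origin + index * spacing``
  (millimetres).  Oblique DICOM geometry (direction cosines other than the
  identity) is rejected with a :class:`~mpcpr.errors.FormatError` rather
  than silently mis-rendered.
* Attenuation is in Hounsfield units, clipped to ``[-1024, 4000]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from mpcpr.errors import FormatError, UsageError

HU_MIN = -1024.0
HU_MAX = 4000.0


class WorldPoint(NamedTuple):
    """A point in world (scanner) coordinates, millimetres."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


def as_points(points) -> np.ndarray:
    """Coerce a point / sequence of points into an (N, 3) float array."""
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[-1] != 3:
        raise UsageError(f"points must have 3 coordinates, got shape {arr.shape}")
    return arr


@dataclass
class Volume:
    """A 3-D CT attenuation grid with physical spacing and origin.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation in Hounsfield units.
    spacing : tuple of 3 floats
        Voxel size in mm along (x, y, z); all strictly positive.
    origin : tuple of 3 floats
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise UsageError("Volume.voxels must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise UsageError(f"spacing must be 3 positive values, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def world_to_voxel(self, points) -> np.ndarray:
        """World mm -> fractional voxel index, (N, 3)."""
        p = as_points(points)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, indices) -> np.ndarray:
        """Fractional voxel index -> world mm, (N, 3)."""
        i = as_points(indices)
        return np.asarray(self.origin) + i * np.asarray(self.spacing)

    def slice_world_z(self, k) -> np.ndarray:
        """World z coordinate (mm) of slice index ``k``."""
        return self.origin[2] + np.asarray(k, dtype=float) * self.spacing[2]

    def contains_world(self, points, margin_vox: float = 0.0) -> np.ndarray:
        """Boolean mask: do these world points fall inside the voxel grid?"""
        idx = self.world_to_voxel(points)
        lo = -0.5 + margin_vox
        hi = np.asarray(self.shape) - 0.5 - margin_vox
        return np.all((idx >= lo) & (idx <= hi), axis=-1)

    def clipped(self) -> "Volume":
        """Return a copy with attenuation clipped to the HU range."""
        return Volume(np.clip(self.voxels, HU_MIN, HU_MAX), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def _detect_format(path: str | os.PathLike) -> str:
    p = Path(path)
    if p.is_dir():
        return "dicom_series"
    name = p.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise UsageError(f"cannot infer volume format from {path!r}; pass format=")


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a CTA volume from a NIfTI file or a DICOM series directory.

    DICOM rescale slope/intercept are applied so voxels are in HU.
    Inconsistent slice spacing within a DICOM series raises
    :class:`FormatError` naming the offending slice.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file or directory: {path}")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise UsageError(f"unknown volume format {fmt!r}")


def write_volume(vol: Volume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume as NIfTI (single file) or a DICOM series (directory)."""
    fmt = format or _detect_format(path) if Path(path).suffix else (format or "dicom_series")
    if fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "dicom_series":
        _write_dicom_series(vol, path)
    else:
        raise UsageError(f"unknown volume format {fmt!r}")


def _read_nifti(path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"not a readable NIfTI file: {path} ({exc})") from exc
    aff = img.affine
    rot = aff[:3, :3]
    diag = np.diag(np.diag(rot))
    if not np.allclose(rot, diag, atol=1e-4) or np.any(np.diag(rot) <= 0):
        raise FormatError(
            "oblique or flipped NIfTI orientation is not supported; "
            "the affine must be a positive diagonal scaling"
        )
    spacing = tuple(float(v) for v in np.diag(rot))
    origin = tuple(float(v) for v in aff[:3, 3])
    data = np.asarray(img.get_fdata(dtype=np.float32))
    return Volume(data, spacing, origin)


def _write_nifti(vol: Volume, path) -> None:
    import nibabel as nib

    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), aff)
    nib.save(img, str(path))


# DICOM: secondary-capture-style series with rescale tags so stored values
# invert exactly to integer HU.
_DICOM_INTERCEPT = -1024.0


def _write_dicom_series(vol: Volume, dirpath) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    out = Path(dirpath)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    stored = np.round(np.clip(vol.voxels, HU_MIN, HU_MAX) - _DICOM_INTERCEPT).astype(np.uint16)
    for k in range(vol.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(vol.origin[0]),
            float(vol.origin[1]),
            float(vol.origin[2] + k * vol.spacing[2]),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # PixelSpacing is (row spacing, column spacing) = (y, x)
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = _DICOM_INTERCEPT
        ds.Rows = vol.shape[1]
        ds.Columns = vol.shape[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        pydicom.dcmwrite(out / f"slice_{k:04d}.dcm", ds, enforce_file_format=True)


def _read_dicom_series(dirpath) -> Volume:
    import pydicom

    files = sorted(
        p for p in Path(dirpath).iterdir() if p.is_file() and p.suffix.lower() == ".dcm"
    )
    if not files:
        raise FormatError(f"no .dcm files in {dirpath}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"unreadable DICOM slice {f.name}: {exc}") from exc
        slices.append((f.name, ds))
    slices.sort(key=lambda t: float(t[1].ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(z) > 1:
        dz = np.diff(z)
        if np.any(dz <= 0):
            bad = slices[int(np.argmax(dz <= 0)) + 1][0]
            raise FormatError(f"duplicate or non-increasing slice position at {bad}")
        if not np.allclose(dz, dz[0], atol=1e-3):
            bad = slices[int(np.argmax(~np.isclose(dz, dz[0], atol=1e-3))) + 1][0]
            raise FormatError(f"inconsistent slice spacing at {bad}")
        sz = float(dz[0])
    else:
        sz = float(getattr(slices[0][1], "SliceThickness", 1.0))
    first = slices[0][1]
    orient = [float(v) for v in getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-4):
        raise FormatError("oblique DICOM orientation is not supported")
    sy, sx = (float(v) for v in first.PixelSpacing)
    planes = []
    for name, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float32) * slope + intercept
        planes.append(arr.T)  # (rows=y, cols=x) -> (x, y)
    vox = np.stack(planes, axis=2)
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    return Volume(vox, (sx, sy, sz), origin)


# ---------------------------------------------------------------------------
# 2-D reformatted-image I/O (DICOM secondary capture, 16/8-bit PNG)
# ---------------------------------------------------------------------------

PNG16_OFFSET = 1024  # PNG16 stores HU + 1024 as unsigned 16-bit: lossless


def write_image(img, path, format: str, window: tuple[float, float] | None = None) -> None:
    """Write a :class:`~mpcpr.render.ReformattedImage` (or bare HU grid).

    Parameters
    ----------
    format : {"dicom", "png16", "png8"}
        ``dicom`` and ``png16`` are losslessly invertible to integer HU;
        ``png8`` applies a linear ``(center, width)`` window and requires one.
    """
    pixels = np.asarray(getattr(img, "pixels", img), dtype=float)
    if format == "png8":
        if window is None:
            raise UsageError("png8 output requires a (center, width) window")
        center, width = window
        lo = center - width / 2.0
        gray = np.clip(np.round((pixels - lo) / width * 255.0), 0, 255).astype(np.uint8)
        _write_png(gray, path)
    elif format == "png16":
        stored = np.clip(np.round(pixels) + PNG16_OFFSET, 0, 65535).astype(np.uint16)
        _write_png(stored, path)
    elif format == "dicom":
        _write_dicom_image(img, pixels, path)
    else:
        raise UsageError(f"unknown image format {format!r}")


def read_image(path, format: str | None = None) -> np.ndarray:
    """Read back an image written by :func:`write_image`, in HU (png16/dicom)."""
    p = Path(path)
    fmt = format or ("dicom" if p.suffix.lower() == ".dcm" else "png16")
    if fmt == "png16":
        from PIL import Image

        arr = np.asarray(Image.open(p), dtype=np.int64)
        return (arr - PNG16_OFFSET).astype(np.float64)
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(p)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return ds.pixel_array.astype(np.float64) * slope + intercept
    raise UsageError(f"unknown image format {fmt!r}")


def _write_png(arr: np.ndarray, path) -> None:
    from PIL import Image

    im = Image.fromarray(arr)
    im.save(str(path))


def _write_dicom_image(img, pixels: np.ndarray, path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    stored = np.round(np.clip(pixels, HU_MIN, HU_MAX) - _DICOM_INTERCEPT).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Modality = "OT"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = _DICOM_INTERCEPT
    ds.Rows, ds.Columns = stored.shape
    angle = getattr(img, "angle", None)
    if angle is not None:
        ds.ImageComments = f"viewing angle {float(angle):+.1f} deg"
    row_sp = getattr(img, "row_spacing", 1.0)
    col_sp = getattr(img, "col_spacing", 1.0)
    ds.PixelSpacing = [float(row_sp), float(col_sp)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(stored).tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
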
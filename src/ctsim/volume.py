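"""Voxel volume data model, Hounsfield-unit conversion, and file I/O.

A CT volume is a structured 3D grid of scalar Hounsfield-unit (HU) samples.
The grid is stored in ``(slice, row, column)`` order (z, y, x), voxel indices
are 0-based, a voxel's world coordinate is its *center*, and the world extent
of an axis with ``n`` voxels at spacing ``s`` is ``n * s`` mm (half-open voxel
cells).  HU values are clamped on ingest to the 12-bit scanner range
``[-1024, 3071]``.

Supported on-disk formats:

* ``dicom_series`` — a directory of single-frame CT slices (read only),
* ``nifti`` — NIfTI-1 via nibabel (read/write),
* ``raw_json`` — a little-endian int16 raw block plus a JSON sidecar with
  shape/spacing/origin, used as a dependency-free test fixture format
  (read/write).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InconsistentSpacingError,
    InvalidParameterError,
    VolumeFormatError,
)

HU_MIN = -1024
HU_MAX = 3071

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "VoxelVolume",
    "BinaryMask",
    "hu_from_attenuation",
    "load_volume",
    "write_volume",
]


def hu_from_attenuation(rho_material: float, rho_water: float) -> float:
    """Convert a linear attenuation coefficient to Hounsfield units.

    ``HU = 1000 * (rho_material - rho_water) / rho_water``, the linear
    remapping that fixes water at 0 HU and air (zero attenuation) at
    -1000 HU.

    Parameters
    ----------
    rho_material : float
        Attenuation coefficient of the material in the voxel. Must be >= 0.
    rho_water : float
        Attenuation coefficient of water. Must be > 0.
    """
    if not rho_water > 0:
        raise InvalidParameterError(f"rho_water must be > 0, got {rho_water}")
    if rho_material < 0:
        raise InvalidParameterError(
            f"rho_material must be >= 0, got {rho_material}"
        )
    # written as 1000*(ratio - 1) so the anchors (water -> 0, air -> -1000)
    # are exact in floating point
    return 1000.0 * (rho_material / rho_water - 1.0)


@dataclass
class VoxelVolume:
    """A 3D scalar grid of HU values with anisotropic spacing.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU samples in (slice, row, column) order.
    spacing : tuple of float
        (dz, dy, dx) voxel spacing in mm, all > 0.
    origin : tuple of float
        World position (z, y, x) in mm of the *corner* of voxel (0, 0, 0);
        voxel centers sit at ``origin + (index + 0.5) * spacing``.
    bits : int
        Intended storage depth (informational; 12 covers the HU range).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bits: int = 12

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise InvalidParameterError(
                f"volume data must be 3D, got {data.ndim}D"
            )
        nz, ny, nx = data.shape
        if nz < 1 or ny < 2 or nx < 2:
            raise InvalidParameterError(
                f"volume needs >=1 slice and >=2 rows/cols, got {data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(
                f"spacing must be 3 positive values, got {self.spacing}"
            )
        self.origin = tuple(float(o) for o in self.origin)
        # clamp-on-ingest to the 12-bit scanner range
        self.data = np.clip(data, HU_MIN, HU_MAX)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """World extent (z, y, x) in mm: n * spacing per axis."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """World mm coordinates (z, y, x) of voxel-center(s) at float index."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Fractional voxel index of world mm coordinate(s)."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5


@dataclass
class BinaryMask:
    """Object/background labeling congruent with a volume or one slice.

    ``data`` holds {0, 1} as uint8; 2D for a single slice, 3D for a volume.
    ``spacing`` is inherited from the source grid ((dy, dx) for a slice).
    """

    data: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim not in (2, 3):
            raise InvalidParameterError("mask must be 2D or 3D")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise InvalidParameterError("mask values must be in {0, 1}")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != data.ndim or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(
                f"mask spacing must match dimensionality, got {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("dicom_series", "nifti", "raw_json")


def load_volume(path: str, format: str | None = None) -> VoxelVolume:
    """Read a volume from disk.

    ``format`` is one of ``dicom_series`` (a directory of CT slices),
    ``nifti`` or ``raw_json``; when omitted it is inferred from the path
    (directory -> dicom_series, ``.nii``/``.nii.gz`` -> nifti,
    ``.json`` -> raw_json).
    """
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise InvalidParameterError(f"unknown volume format {format!r}")
    if format == "raw_json":
        return _load_raw_json(path)
    if format == "nifti":
        return _load_nifti(path)
    return _load_dicom_series(path)


def write_volume(volume: VoxelVolume, path: str, format: str | None = None) -> None:
    """Write a volume to disk (``nifti`` or ``raw_json``).

    Round-trips are bit-exact for integer HU data in both formats.
    """
    if format is None:
        format = _infer_format(path, for_write=True)
    if format == "raw_json":
        _write_raw_json(volume, path)
    elif format == "nifti":
        _write_nifti(volume, path)
    elif format == "dicom_series":
        raise InvalidParameterError("dicom_series is read-only")
    else:
        raise InvalidParameterError(f"unknown volume format {format!r}")


def _infer_format(path: str, for_write: bool = False) -> str:
    p = str(path)
    if p.endswith(".json"):
        return "raw_json"
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return "nifti"
    if not for_write and os.path.isdir(p):
        return "dicom_series"
    raise InvalidParameterError(f"cannot infer volume format from {path!r}")


# -- raw_json fixture format -------------------------------------------------

def _raw_path_for(json_path: str, sidecar: dict | None = None) -> str:
    base = os.path.splitext(json_path)[0]
    if sidecar is not None and "raw" in sidecar:
        return os.path.join(os.path.dirname(json_path), sidecar["raw"])
    return base + ".raw"


def _load_raw_json(path: str) -> VoxelVolume:
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        with open(path) as fh:
            meta = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise VolumeFormatError(f"corrupt raw_json sidecar {path}: {exc}") from exc
    try:
        shape = tuple(int(n) for n in meta["shape"])
        spacing = tuple(float(s) for s in meta["spacing"])
        origin = tuple(float(o) for o in meta.get("origin", (0, 0, 0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise VolumeFormatError(f"invalid raw_json metadata in {path}") from exc
    raw_path = _raw_path_for(path, meta)
    if not os.path.exists(raw_path):
        raise VolumeFormatError(f"raw block missing: {raw_path}")
    data = np.fromfile(raw_path, dtype="<i2")
    if data.size != int(np.prod(shape)):
        raise VolumeFormatError(
            f"raw block size {data.size} does not match shape {shape}"
        )
    return VoxelVolume(
        data.reshape(shape).astype(np.int16),
        spacing=spacing,
        origin=origin,
        bits=int(meta.get("bits", 12)),
    )


def _write_raw_json(volume: VoxelVolume, path: str) -> None:
    raw_path = _raw_path_for(path)
    meta = {
        "shape": list(volume.shape),
        "spacing": list(volume.spacing),
        "origin": list(volume.origin),
        "dtype": "int16",
        "byte_order": "little",
        "bits": volume.bits,
        "raw": os.path.basename(raw_path),
    }
    data = np.rint(np.asarray(volume.data)).astype("<i2")
    try:
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)
        data.tofile(raw_path)
    except OSError as exc:
        raise VolumeFormatError(f"cannot write {path}: {exc}") from exc


# -- NIfTI -------------------------------------------------------------------

def _load_nifti(path: str) -> VoxelVolume:
    import nibabel as nib

    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises various types
        raise VolumeFormatError(f"cannot read NIfTI {path}: {exc}") from exc
    if arr.ndim != 3:
        raise VolumeFormatError(f"NIfTI volume must be 3D, got {arr.ndim}D")
    zooms = img.header.get_zooms()[:3]
    # nibabel axis order is (x, y, z); ours is (z, y, x)
    data = np.transpose(arr, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    off = img.affine[:3, 3]
    origin = (float(off[2]), float(off[1]), float(off[0]))
    return VoxelVolume(data, spacing=spacing, origin=origin)


def _write_nifti(volume: VoxelVolume, path: str) -> None:
    import nibabel as nib

    affine = np.diag([volume.spacing[2], volume.spacing[1], volume.spacing[0], 1.0])
    affine[:3, 3] = (volume.origin[2], volume.origin[1], volume.origin[0])
    data = np.rint(np.asarray(volume.data)).astype(np.int16)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms(
        (volume.spacing[2], volume.spacing[1], volume.spacing[0])
    )
    try:
        nib.save(img, path)
    except OSError as exc:
        raise VolumeFormatError(f"cannot write {path}: {exc}") from exc


# -- DICOM series ------------------------------------------------------------

def _load_dicom_series(path: str) -> VoxelVolume:
    import pydicom

    if not os.path.isdir(path):
        raise VolumeFormatError(f"not a DICOM series directory: {path}")
    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise VolumeFormatError(f"cannot parse DICOM file {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise VolumeFormatError(f"no DICOM image slices found in {path}")

    def _zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    slices.sort(key=_zpos)
    zs = np.array([_zpos(ds) for ds in slices])
    if len(slices) > 1:
        dz_all = np.diff(zs)
        dz = float(np.median(dz_all))
        if dz <= 0:
            raise InconsistentSpacingError("duplicate or unordered slice positions")
        if np.any(np.abs(dz_all - dz) > 0.01 * dz):
            raise InconsistentSpacingError(
                f"non-uniform slice spacing: steps {sorted(set(np.round(dz_all, 3)))}"
            )
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    first = slices[0]
    try:
        dy, dx = (float(v) for v in first.PixelSpacing)
    except (AttributeError, TypeError, ValueError) as exc:
        raise VolumeFormatError("DICOM slice lacks PixelSpacing") from exc
    rows = []
    for ds in slices:
        try:
            arr = ds.pixel_array.astype(np.float64)
        except Exception as exc:
            raise VolumeFormatError(
                f"unsupported pixel representation: {exc}"
            ) from exc
        if arr.shape != slices[0].pixel_array.shape:
            raise VolumeFormatError("slices have mismatched matrix sizes")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        rows.append(arr * slope + intercept)
    data = np.rint(np.stack(rows)).astype(np.int16)
    ox = oy = 0.0
    if hasattr(first, "ImagePositionPatient"):
        ox = float(first.ImagePositionPatient[0])
        oy = float(first.ImagePositionPatient[1])
    return VoxelVolume(
        data, spacing=(dz, dy, dx), origin=(float(zs[0]), oy, ox)
    )
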
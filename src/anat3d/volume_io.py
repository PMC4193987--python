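"""Volumetric image data model and MetaImage/NRRD input-output.

The in-memory grid convention used by every module in this package:

* ``Volume.data`` is indexed ``data[i, j, k]`` with ``i`` along x, ``j``
  along y and ``k`` along z.  For a C-contiguous array this makes z the
  fastest-varying axis in memory; the index order ``(x, y, z)`` is what
  all geometric formulas below refer to.
* Voxels are node-centered samples: the physical position of index
  ``(i, j, k)`` is ``origin + (i * sx, j * sy, k * sz)`` in millimetres.
* Intensities are Hounsfield units (HU), stored on disk as signed 16-bit
  integers (the clinical CT range of roughly -1024..3071 fits) and
  widened to wider integer or float types in memory as needed.

Files are read and written through SimpleITK, which handles the
MetaImage (``.mhd`` + ``.raw``) and NRRD containers; the on-disk axis
order follows each container's own declaration and is transposed to the
convention above on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "Mask",
    "LabelMap",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_dicom_series",
]

_SUPPORTED_EXTENSIONS = (".mhd", ".mha", ".nrrd")


class VolumeIOError(RuntimeError):
    """Raised when a volume file is missing, malformed or unsupported."""


@dataclass
class Volume:
    """A 3D scalar grid of HU values with physical geometry.

    Parameters
    ----------
    data
        3D array indexed ``[i, j, k]`` along (x, y, z); HU values.
    spacing
        Millimetres per voxel step, ``(sx, sy, sz)``; all positive.
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("Volume.data must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm positions."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def same_grid(self, other: "Volume | Mask | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Mask:
    """Boolean grid aligned to a :class:`Volume` geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("Mask.data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @classmethod
    def like(cls, vol: "Volume", data: np.ndarray) -> "Mask":
        if data.shape != vol.shape:
            raise ValueError(f"mask shape {data.shape} != grid shape {vol.shape}")
        return cls(data=data, spacing=vol.spacing, origin=vol.origin)

    def same_grid(self, other: "Volume | Mask | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMap:
    """Non-negative integer grid with a label-id -> structure-name table.

    Label 0 is reserved for background and never appears in ``names``.
    """

    data: np.ndarray
    names: dict[int, str]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap.data must be 3D")
        if np.any(self.data < 0):
            raise ValueError("labels must be non-negative")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from names table")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask_for(self, name: str) -> Mask:
        """Binary mask of the structure called ``name``."""
        ids = [i for i, n in self.names.items() if n == name]
        if not ids:
            raise KeyError(f"no label named {name!r}")
        return Mask(np.isin(self.data, ids), self.spacing, self.origin)

    def same_grid(self, other: "Volume | Mask | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _check_extension(path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXTENSIONS:
        raise VolumeIOError(
            f"unsupported volume format {ext!r} for {path!r}; "
            f"expected one of {_SUPPORTED_EXTENSIONS}"
        )


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a MetaImage or NRRD volume; format detected by extension.

    HU values are returned unchanged; spacing and origin come from the
    file header.  Raises :class:`VolumeIOError` for missing files,
    malformed headers (including truncated raw payloads) and unsupported
    formats, never returning a partial volume.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"volume file not found: {path!r}")
    _check_extension(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK reports header/payload problems here
        raise VolumeIOError(f"failed to read {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeIOError(f"{path!r} is {img.GetDimension()}D; only 3D volumes supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Volume(data=data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a volume as MetaImage or NRRD (by extension), losslessly for
    integer HU data (stored as signed 16-bit, little-endian)."""
    path = os.fspath(path)
    _check_extension(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise VolumeIOError(f"parent directory does not exist: {parent!r}")
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.bool_):
        lo, hi = np.iinfo(np.int16).min, np.iinfo(np.int16).max
        if data.min() < lo or data.max() > hi:
            raise VolumeIOError(
                f"integer HU range [{data.min()}, {data.max()}] exceeds signed 16-bit storage"
            )
        out = data.astype(np.int16)
    else:
        out = data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(out.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    try:
        sitk.WriteImage(img, path)
    except RuntimeError as exc:
        raise VolumeIOError(f"failed to write {path!r}: {exc}") from exc


def read_dicom_series(directory: str | os.PathLike) -> Volume:
    """Read a DICOM series from a directory (experimental, read-only)."""
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise VolumeIOError(f"DICOM directory not found: {directory!r}")
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(directory)
    if not files:
        raise VolumeIOError(f"no DICOM series found in {directory!r}")
    reader.SetFileNames(files)
    try:
        img = reader.Execute()
    except RuntimeError as exc:
        raise VolumeIOError(f"failed to read DICOM series from {directory!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    return Volume(
        data=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
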
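"""Geometry-aware 3D volumes, binary masks and labeled point sets.

Conventions used throughout the package:

* physical coordinates are millimetres; voxel indices are 0-based and refer
  to voxel *centers*;
* ``voxels`` arrays are indexed ``[ix, iy, iz]`` (shape equals ``size``);
* ``voxel -> physical``:  ``p = origin + direction @ (index * spacing)``.

Volumes are exchanged on disk as NIfTI (``.nii``/``.nii.gz``) or MetaImage
(``.mha``/``.mhd``); point sets as CSV with header ``label,x_mm,y_mm,z_mm``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import GeometryError, ParameterError, VolumeFormatError

_SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")

__all__ = [
    "Grid",
    "ImageVolume",
    "BinaryMask",
    "LabeledPointSet",
    "read_volume",
    "write_volume",
    "resample",
]


@dataclass(frozen=True)
class Grid:
    """Sampling geometry of a 3D volume: size, spacing, origin, direction.

    ``direction`` is a 3x3 orthonormal matrix of axis cosines mapping index
    axes onto physical axes. Positions refer to voxel centers.
    """

    size: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", tuple(int(s) for s in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if any(s <= 0 for s in self.size):
            raise GeometryError(f"non-positive grid size {self.size}")
        if any(s <= 0.0 for s in self.spacing):
            raise GeometryError(f"non-positive spacing {self.spacing}")
        if np.abs(d.T @ d - np.eye(3)).max() >= 1e-6:
            raise GeometryError("direction matrix is not orthonormal to 1e-6")

    # -- coordinate transforms -------------------------------------------
    def voxel_to_physical(self, index) -> np.ndarray:
        """Physical position (mm) of a (possibly fractional) voxel index."""
        idx = np.asarray(index, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + scaled @ self.direction.T

    def physical_to_voxel(self, position) -> np.ndarray:
        """Continuous voxel index of a physical position (mm)."""
        p = np.asarray(position, dtype=float)
        local = (p - np.asarray(self.origin)) @ self.direction
        return local / np.asarray(self.spacing)

    @property
    def has_identity_direction(self) -> bool:
        return bool(np.allclose(self.direction, np.eye(3), atol=1e-12))

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (pmin, pmax) of voxel centers, mm.

        Only meaningful for identity direction matrices, which is all the
        registration pipeline supports.
        """
        pmin = np.asarray(self.origin, dtype=float)
        pmax = pmin + (np.asarray(self.size) - 1) * np.asarray(self.spacing)
        return pmin, pmax

    def voxel_centers(self, step: int = 1) -> np.ndarray:
        """Physical centers of every ``step``-th voxel, as an (N, 3) array."""
        axes = [np.arange(0, n, step, dtype=float) for n in self.size]
        ii = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        return self.voxel_to_physical(ii)

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ImageVolume:
    """A 3D scalar image (HU-like intensities) with physical geometry."""

    voxels: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != tuple(self.grid.size):
            raise GeometryError(
                f"voxel array shape {self.voxels.shape} != grid size {self.grid.size}"
            )

    # geometry pass-throughs so callers rarely need .grid
    @property
    def size(self):
        return self.grid.size

    @property
    def spacing(self):
        return self.grid.spacing

    @property
    def origin(self):
        return self.grid.origin

    @property
    def direction(self):
        return self.grid.direction

    def voxel_to_physical(self, index):
        return self.grid.voxel_to_physical(index)

    def physical_to_voxel(self, position):
        return self.grid.physical_to_voxel(position)

    def copy(self) -> "ImageVolume":
        return type(self)(self.voxels.copy(), self.grid)


class BinaryMask(ImageVolume):
    """A boolean structure mask sharing :class:`ImageVolume` geometry."""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            self.voxels = self.voxels > 0.5
        super().__post_init__()

    @property
    def volume_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class LabeledPointSet:
    """Labeled physical points (mm), e.g. fiducial marker tips.

    Fiducial sets use paired labels ``<id>_top`` / ``<id>_bottom`` per
    implanted marker. Labels must be unique within a set.
    """

    labels: list[str]
    points: np.ndarray
    frame: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise ParameterError("label/point count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("labels must be unique within a point set")

    def __len__(self) -> int:
        return len(self.labels)

    def position(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x_mm", "y_mm", "z_mm"])
            for label, p in zip(self.labels, self.points):
                writer.writerow([label, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])

    @classmethod
    def from_csv(cls, path, frame: str = "") -> "LabeledPointSet":
        labels, pts = [], []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"label", "x_mm", "y_mm", "z_mm"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise VolumeFormatError(
                    f"{path}: point-set CSV must have header label,x_mm,y_mm,z_mm"
                )
            for row in reader:
                labels.append(row["label"])
                pts.append([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
        return cls(labels, np.asarray(pts), frame=frame)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED_EXTENSIONS):
        raise VolumeFormatError(
            f"{path}: unsupported extension (expected one of {_SUPPORTED_EXTENSIONS})"
        )


def read_volume(path, dtype_hint: str = "intensity") -> ImageVolume | BinaryMask:
    """Read a NIfTI or MetaImage volume.

    ``dtype_hint="mask"`` binarizes via ``value > 0.5`` and returns a
    :class:`BinaryMask`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"{path}: file does not exist")
    _check_extension(path)
    if dtype_hint not in ("intensity", "mask"):
        raise ParameterError(f"dtype_hint must be 'intensity' or 'mask', got {dtype_hint!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise VolumeFormatError(f"{path}: unreadable volume ({exc})") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    try:
        grid = Grid(img.GetSize(), img.GetSpacing(), img.GetOrigin(), direction)
    except GeometryError as exc:
        raise GeometryError(f"{path}: {exc}") from exc
    if dtype_hint == "mask":
        return BinaryMask(voxels, grid)
    return ImageVolume(voxels.astype(np.float64, copy=False), grid)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume; masks are stored as 8-bit integers (0/1)."""
    path = Path(path)
    _check_extension(path)
    if not path.parent.exists():
        raise VolumeFormatError(f"{path}: parent directory does not exist")
    voxels = vol.voxels
    if isinstance(vol, BinaryMask) or voxels.dtype == bool:
        voxels = voxels.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(np.asarray(vol.direction, dtype=float).ravel()))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"{path}: could not write volume ({exc})") from exc


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(
    vol: ImageVolume,
    reference: Grid,
    interp: str = "linear",
    fill: float | None = None,
) -> ImageVolume | BinaryMask:
    """Resample ``vol`` onto ``reference`` geometry.

    ``interp`` is ``"linear"`` or ``"nearest"``; masks require nearest.
    Samples falling outside ``vol``'s grid take ``fill`` (default 0 for
    masks; required explicitly for intensity images so field-of-view
    differences are never silently zero-filled).
    """
    is_mask = isinstance(vol, BinaryMask)
    if interp not in ("linear", "nearest"):
        raise ParameterError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if is_mask and interp != "nearest":
        raise ParameterError("binary masks must be resampled with nearest interpolation")
    if fill is None:
        if is_mask:
            fill = 0.0
        else:
            raise ParameterError("an explicit out-of-domain fill value is required for images")

    centers = reference.voxel_centers()
    idx = vol.grid.physical_to_voxel(centers)  # (N, 3) continuous indices
    n = np.asarray(vol.grid.size)
    inside = np.all((idx >= 0.0) & (idx <= n - 1), axis=1)
    order = 1 if interp == "linear" else 0
    src = vol.voxels.astype(np.float64, copy=False)
    values = ndimage.map_coordinates(src, idx.T, order=order, mode="nearest")
    values[~inside] = fill
    out = values.reshape(reference.size)
    if is_mask:
        return BinaryMask(out > 0.5, reference)
    return ImageVolume(out, reference)
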
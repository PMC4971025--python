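"""Label, intensity, and posterior volumes with geometry metadata.

Volumes are held as numpy arrays indexed ``voxels[x, y, z]`` (0-based index
space). All algorithms downstream operate purely in index space: structuring
elements are defined in voxel units, so anisotropic voxel spacing makes a
"ball" physically anisotropic. Geometry (spacing, origin, direction) is
carried through I/O untouched and used only to enforce the co-registration
contract between companion volumes.

I/O goes through SimpleITK, which handles both of 3D Slicer's native
dialects: NIfTI-1 (``.nii``/``.nii.gz``) and NRRD (``.nrrd``/``.nhdr``).
SimpleITK arrays arrive in (z, y, x) order and are transposed on the way in
and out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .errors import GeometryMismatchError, LabelTypeError, VolumeFormatError

__all__ = [
    "VolumeGeometry",
    "LabelVolume",
    "IntensityVolume",
    "PosteriorVolume",
    "read_label_volume",
    "read_intensity_volume",
    "read_posterior_volume",
    "write_label_volume",
    "write_intensity_volume",
    "write_posterior_volume",
    "assert_coregistered",
]

_IDENTITY = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

#: Default tolerance for the co-registration contract.
DEFAULT_GEOMETRY_TOL = 1e-5


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel-grid geometry: shape, spacing (mm/voxel), origin (mm), direction.

    The direction matrix is row-major 3x3 and must be orthonormal within
    1e-6.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, float, float], ...] = _IDENTITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(
            self, "direction", tuple(tuple(float(x) for x in row) for row in self.direction)
        )
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3, 3) or not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise ValueError("direction must be an orthonormal 3x3 matrix (tol 1e-6)")

    def agrees_with(self, other: "VolumeGeometry", tolerance: float) -> str | None:
        """Return None if geometries match within tolerance, else a description."""
        if self.shape != other.shape:
            return f"shape {self.shape} vs {other.shape}"
        for name in ("spacing", "origin"):
            a, b = getattr(self, name), getattr(other, name)
            if max(abs(x - y) for x, y in zip(a, b)) > tolerance:
                return f"{name} {a} vs {b}"
        da, db = np.asarray(self.direction), np.asarray(other.direction)
        if np.abs(da - db).max() > tolerance:
            return f"direction {self.direction} vs {other.direction}"
        return None


def _default_geometry(shape: tuple[int, ...]) -> VolumeGeometry:
    return VolumeGeometry(shape=tuple(shape))


@dataclass
class LabelVolume:
    """A 3D grid of non-negative integer label IDs plus geometry.

    ``background_id`` names the label treated as background by convention
    (default 0); algorithmically it is an ordinary label.
    """

    voxels: np.ndarray
    geometry: VolumeGeometry = None  # type: ignore[assignment]
    background_id: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise VolumeFormatError(f"label volume must be 3D, got ndim={arr.ndim}")
        if np.issubdtype(arr.dtype, np.floating):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.abs(arr - rounded).max() > 1e-6:
                raise LabelTypeError("label volume holds non-integral values")
            arr = rounded
        if arr.size and arr.min() < 0:
            raise LabelTypeError("label IDs must be non-negative")
        self.voxels = arr.astype(np.uint32, copy=False)
        if self.geometry is None:
            self.geometry = _default_geometry(self.voxels.shape)
        if self.geometry.shape != self.voxels.shape:
            raise GeometryMismatchError(
                f"geometry shape {self.geometry.shape} != array shape {self.voxels.shape}"
            )

    @property
    def label_ids(self) -> list[int]:
        """Sorted list of label IDs present in the volume."""
        return [int(v) for v in np.unique(self.voxels)]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.geometry, self.background_id)


@dataclass
class IntensityVolume:
    """A co-registered 3D scalar grid for one imaging modality (e.g. T1w)."""

    voxels: np.ndarray
    modality_name: str = "intensity"
    geometry: VolumeGeometry = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3:
            raise VolumeFormatError(f"intensity volume must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise VolumeFormatError("intensity volume contains NaN or Inf")
        self.voxels = arr
        if self.geometry is None:
            self.geometry = _default_geometry(arr.shape)
        if self.geometry.shape != arr.shape:
            raise GeometryMismatchError(
                f"geometry shape {self.geometry.shape} != array shape {arr.shape}"
            )


@dataclass
class PosteriorVolume:
    """A 3D probability (or binary-mask) grid with values in [0, 1]."""

    voxels: np.ndarray
    geometry: VolumeGeometry = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3:
            raise VolumeFormatError(f"posterior volume must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)) or (arr.size and (arr.min() < 0 or arr.max() > 1)):
            raise VolumeFormatError("posterior values must be finite and within [0, 1]")
        self.voxels = arr
        if self.geometry is None:
            self.geometry = _default_geometry(arr.shape)
        if self.geometry.shape != arr.shape:
            raise GeometryMismatchError(
                f"geometry shape {self.geometry.shape} != array shape {arr.shape}"
            )


def _read_image(path: str | os.PathLike) -> tuple[np.ndarray, VolumeGeometry]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError(
            f"{path!r}: expected a scalar 3D volume, got "
            f"{img.GetDimension()}D x {img.GetNumberOfComponentsPerPixel()} components"
        )
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    d = img.GetDirection()
    geom = VolumeGeometry(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=(tuple(d[0:3]), tuple(d[3:6]), tuple(d[6:9])),
    )
    return arr, geom


def _write_image(arr: np.ndarray, geom: VolumeGeometry, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(geom.spacing)
    img.SetOrigin(geom.origin)
    img.SetDirection(tuple(x for row in geom.direction for x in row))
    try:
        sitk.WriteImage(img, path)
    except Exception as exc:
        raise VolumeFormatError(f"cannot write {path!r}: {exc}") from exc


def read_label_volume(path: str | os.PathLike, background_id: int = 0) -> LabelVolume:
    """Read a NIfTI-1 or NRRD label map.

    Float-stored label maps are accepted only when every value is integral
    within 1e-6, then cast to unsigned 32-bit (atlas IDs like 15000 exceed
    8 bits).
    """
    arr, geom = _read_image(path)
    return LabelVolume(arr, geometry=geom, background_id=background_id)


def read_intensity_volume(path: str | os.PathLike, modality_name: str) -> IntensityVolume:
    """Read a scalar 3D intensity volume; NaN/Inf anywhere is an error."""
    arr, geom = _read_image(path)
    return IntensityVolume(arr, modality_name=modality_name, geometry=geom)


def read_posterior_volume(path: str | os.PathLike) -> PosteriorVolume:
    """Read a probability/mask volume; values must lie in [0, 1]."""
    arr, geom = _read_image(path)
    return PosteriorVolume(arr, geometry=geom)


def write_label_volume(v: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label map; a round-trip read returns a voxel-identical grid."""
    _write_image(v.voxels.astype(np.uint32, copy=False), v.geometry, path)


def write_intensity_volume(v: IntensityVolume, path: str | os.PathLike) -> None:
    _write_image(v.voxels, v.geometry, path)


def write_posterior_volume(v: PosteriorVolume, path: str | os.PathLike) -> None:
    _write_image(v.voxels, v.geometry, path)


def assert_coregistered(
    volumes: Sequence[LabelVolume | IntensityVolume | PosteriorVolume],
    tolerance: float = DEFAULT_GEOMETRY_TOL,
) -> None:
    """Raise GeometryMismatchError unless all volumes share one voxel grid.

    Shapes must be equal and spacing/origin/direction must agree within
    ``tolerance``; the error names the first offending pair.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to compare")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        why = ref.geometry.agrees_with(v.geometry, tolerance)
        if why is not None:
            raise GeometryMismatchError(
                f"volume 0 and volume {i} are not co-registered: {why}"
            )
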
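"""SUV volume data model, SUV conversion, and NIfTI-1 input/output.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` with 0-based voxel coordinates; every
  coordinate reported by the pipeline (seed points, operator clicks) uses
  this order.
* ``spacing`` is the per-axis voxel size in mm, also ordered ``(z, y, x)``.
  The core ratio algorithm operates purely in voxel units; spacing matters
  only to the phantom point-spread function and to file round-trips.
* SUV values are dimensionless and non-negative.  Volumes that are already
  in SUV units need no acquisition metadata.

On disk, volumes are stored as standard NIfTI-1 with the array transposed
to the ``(x, y, z)`` layout nibabel expects, so files interoperate with
other viewers; masks are written as unsigned 8-bit 0/1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import EmptyRegionError, InvalidMetadataError, VolumeIOError

#: Roles a voxel mask can play in the pipeline.
MASK_ROLES = ("lesion", "eroded_lesion", "surface", "necrotic_core", "tumor", "generic")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection metadata needed to convert activity concentration to SUV.

    Parameters
    ----------
    injected_activity_bq:
        Injected tracer activity in Bq (e.g. 370 MBq = ``370e6``).
    body_weight_kg:
        Patient body weight in kg.
    """

    injected_activity_bq: float
    body_weight_kg: float

    def __post_init__(self) -> None:
        for name in ("injected_activity_bq", "body_weight_kg"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidMetadataError(f"{name} must be finite and > 0, got {value!r}")


@dataclass
class SUVVolume:
    """A 3D grid of SUV values with physical voxel spacing.

    ``data`` is stored as float64, indexed ``(z, y, x)``.  All values must
    be finite and non-negative; each axis must have length >= 1.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with each axis >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VOIMask:
    """A binary voxel mask on the same grid as its parent volume."""

    data: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def n(self) -> int:
        """Number of voxels in the mask."""
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def suv_from_activity(
    activity_bq_ml: np.ndarray,
    meta: AcquisitionMeta,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SUVVolume:
    """Convert an activity-concentration volume (Bq/mL) to SUV.

    SUV(v) = activity(v) / (injected_activity / (body_weight * 1000)),
    i.e. activity normalised by injected dose per gram of body mass.
    The conversion is linear in activity and inversely linear in dose;
    shape and spacing are preserved.
    """
    activity = np.asarray(activity_bq_ml, dtype=np.float64)
    if not np.all(np.isfinite(activity)):
        raise ValueError("activity volume contains non-finite values")
    if np.any(activity < 0):
        raise ValueError("activity concentrations must be non-negative")
    denom = meta.injected_activity_bq / (meta.body_weight_kg * 1000.0)
    return SUVVolume(activity / denom, spacing=spacing, origin=origin)


def suv_max(vol: SUVVolume, voi: VOIMask) -> float:
    """Maximum SUV over the voxels of a volume of interest."""
    if voi.shape != vol.shape:
        raise ValueError(f"mask shape {voi.shape} != volume shape {vol.shape}")
    if voi.n == 0:
        raise EmptyRegionError("cannot take SUVmax over an empty VOI")
    return float(vol.data[voi.data].max())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing_zyx, origin_zyx) -> np.ndarray:
    sx, sy, sz = spacing_zyx[::-1]
    ox, oy, oz = origin_zyx[::-1]
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def _load_3d(path) -> tuple[np.ndarray, tuple, tuple]:
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"could not read NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeIOError(f"expected a 3D volume, got {arr.ndim}D data in {path}")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms[::-1])
    origin = tuple(float(t) for t in img.affine[:3, 3][::-1])
    return arr.T, spacing, origin  # file (x, y, z) -> package (z, y, x)


def read_volume(path) -> SUVVolume:
    """Read a 3D NIfTI-1 scalar volume as an :class:`SUVVolume`."""
    arr, spacing, origin = _load_3d(path)
    return SUVVolume(np.asarray(arr, dtype=np.float64), spacing=spacing, origin=origin)


def write_volume(vol: SUVVolume, path) -> None:
    """Write a volume as float32 NIfTI-1 (data transposed to x, y, z on disk)."""
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32).T, _affine(vol.spacing, vol.origin)
    )
    nib.save(img, str(path))


def read_mask(path, role: str = "generic") -> VOIMask:
    """Read a NIfTI mask; any nonzero voxel is part of the mask."""
    arr, _, _ = _load_3d(path)
    return VOIMask(arr != 0, role=role)


def write_mask(
    mask: VOIMask,
    path,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> None:
    """Write a mask as unsigned 8-bit 0/1 NIfTI-1."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8).T, _affine(spacing, origin))
    nib.save(img, str(path))
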
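"""Semiautomatic lesion VOI extraction (mask M1).

The lesion mask is the 26-connected component of supra-threshold voxels
(SUV >= 2.5 by default) containing an operator-supplied approximate point,
with enclosed photopenic cavities filled in.  Filling matters: a malignant
lesion with central coagulative necrosis is a high-uptake rim around a
cold core, and the necrotic-core segmentation downstream must operate
*inside* the lesion VOI — a purely supra-threshold mask would be a hollow
shell that excludes the very region the method quantifies.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import NoLesionError, SeedMismatchError
from .suv_volume import SUVVolume, VOIMask

#: Full 3x3x3 structuring element (26-connectivity).
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _snap_to_supra(supra: np.ndarray, point: tuple[int, int, int]) -> tuple[tuple, float]:
    """Nearest supra-threshold voxel (Euclidean, voxel units).

    Ties are broken lexicographically in (z, y, x); ``np.argwhere`` yields
    coordinates in that order, and ``argmin`` returns the first minimum.
    """
    coords = np.argwhere(supra)
    d2 = ((coords - np.asarray(point)) ** 2).sum(axis=1)
    best = int(np.argmin(d2))
    return tuple(int(c) for c in coords[best]), float(np.sqrt(d2[best]))


def segment_lesion(
    vol: SUVVolume,
    approx_point: tuple[int, int, int],
    threshold: float = 2.5,
    *,
    fill_holes: bool = True,
    max_seed_distance: float = 20.0,
    bounding_box: tuple[tuple[int, int], ...] | None = None,
) -> VOIMask:
    """Segment the lesion mask M1 around an operator point.

    Parameters
    ----------
    vol:
        The SUV volume.
    approx_point:
        Approximate (z, y, x) voxel coordinate inside (or near) the lesion.
        If the point itself is below threshold it is snapped to the nearest
        supra-threshold voxel.
    threshold:
        Inclusive SUV cut for lesion membership (default 2.5).
    fill_holes:
        Fill cavities fully enclosed by the supra-threshold component, so
        that a photopenic necrotic core belongs to the lesion VOI.
    max_seed_distance:
        Maximum snap distance in voxels before the operator point is
        rejected as inconsistent with any lesion.
    bounding_box:
        Optional per-axis ``(lo, hi)`` half-open voxel bounds confining
        the segmentation, to keep the VOI from leaking into an adjacent
        FDG-avid organ (e.g. the bladder).

    Returns
    -------
    VOIMask with role ``"lesion"``.
    """
    point = tuple(int(c) for c in approx_point)
    if len(point) != 3 or any(c < 0 or c >= s for c, s in zip(point, vol.shape)):
        raise ValueError(f"approx_point {approx_point} outside grid of shape {vol.shape}")

    supra = vol.data >= threshold
    if bounding_box is not None:
        box = np.zeros(vol.shape, dtype=bool)
        box[tuple(slice(lo, hi) for lo, hi in bounding_box)] = True
        supra &= box
    if not supra.any():
        raise NoLesionError(f"no voxel reaches SUV threshold {threshold}")

    if not supra[point]:
        point, dist = _snap_to_supra(supra, point)
        if dist > max_seed_distance:
            raise SeedMismatchError(
                f"nearest supra-threshold voxel is {dist:.1f} voxels away "
                f"(limit {max_seed_distance})"
            )

    labels, _ = ndi.label(supra, structure=STRUCT_26)
    component = labels == labels[point]
    if fill_holes:
        component = ndi.binary_fill_holes(component)
    return VOIMask(component, role="lesion")
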
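"""The metabolic tumor/necrosis ratio.

The ratio quantifies coagulative tumor necrosis on FDG PET: an abrupt
photopenic core inside a metabolically active rim (the "hollow ball"
uptake pattern of leiomyosarcoma and STUMP) yields a high surface-to-core
contrast, whereas the gradual hyaline degeneration of benign leiomyomas
does not.  The pipeline is

1. lesion VOI M1 at SUV >= 2.5 (see :mod:`tnrpet.lesion_segmentation`);
2. redigitize the lesion intensities into 16 equally spaced integer bins
   0..15, minimum mapped to 0 and maximum to 15;
3. intensity-weighted gradient magnitude (IWG): gradient of the binned
   image by central differences, times the original SUV image;
4. smooth the IWG with a 3x3x3 averaging kernel, then grayscale-erode
   once (3x3x3 minimum filter);
5. the minimum-IWG voxel (searched within M1 eroded once, so that the
   boundary rind of spurious gradient cannot seed) starts a 6-connected
   region growing at threshold 3x the seed value: the necrotic core VOI;
6. surface tumor VOI = M1 minus M1 eroded k times, with the shell
   thickness k = max(1, round(n^(1/3) * 0.1)) for n lesion voxels;
7. ratio = mean bin over surface VOI / mean bin over core VOI.

In a benign lesion the IWG field is noise-dominated and the growth floods
essentially the whole VOI, so numerator and denominator are both near the
lesion-wide mean and the ratio sits close to 1.  In a necrotic malignant
lesion the seed lands in the flat, cold core, 3x its tiny IWG value cannot
cross the steep rim interface, and the denominator collapses to the
near-zero core bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .errors import (
    DegenerateLesionError,
    EmptyRegionError,
    UndefinedRatioError,
)
from .lesion_segmentation import STRUCT_26, segment_lesion
from .suv_volume import SUVVolume, VOIMask, suv_max

#: 6-connectivity structuring element for the necrotic-core growth.
STRUCT_6 = ndi.generate_binary_structure(3, 1)

N_BINS = 16


@dataclass
class RedigitizedVolume:
    """Integer 0..15 bin values inside the lesion VOI, 0 outside."""

    data: np.ndarray
    source_min: float
    source_max: float


@dataclass
class GradientVolume:
    """Non-negative intensity-weighted gradient magnitude image."""

    data: np.ndarray
    stage: str  # raw | smoothed | eroded


@dataclass
class TNRResult:
    """Full audit record of one metabolic tumor/necrosis ratio computation."""

    ratio: float
    surface_metabolism: float
    core_metabolism: float
    k: int
    n: int
    seed: tuple[int, int, int]
    suv_max: float
    lesion_voi: VOIMask
    m2_voi: VOIMask
    surface_voi: VOIMask
    core_voi: VOIMask
    core_surface_overlap: float
    suv_threshold: float = 2.5
    growth_factor: float = 3.0

    def to_dict(self) -> dict:
        """JSON-serialisable summary (mask voxel counts, not arrays)."""
        return {
            "ratio": self.ratio,
            "surface_metabolism": self.surface_metabolism,
            "core_metabolism": self.core_metabolism,
            "k": self.k,
            "n": self.n,
            "seed_zyx": list(self.seed),
            "suv_max": self.suv_max,
            "core_voxels": self.core_voi.n,
            "surface_voxels": self.surface_voi.n,
            "m2_voxels": self.m2_voi.n,
            "core_surface_overlap": self.core_surface_overlap,
            "suv_threshold": self.suv_threshold,
            "growth_factor": self.growth_factor,
        }


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (for x >= 0: up)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def redigitize(vol: SUVVolume, m1: VOIMask) -> RedigitizedVolume:
    """Map lesion SUVs onto 16 equally spaced integer bins.

    bin(v) = round_half_up(15 * (SUV(v) - min) / (max - min)) for v in M1;
    voxels outside M1 are 0.  The lesion minimum maps to bin 0 and the
    maximum to bin 15 exactly.
    """
    if m1.shape != vol.shape:
        raise ValueError("mask and volume shapes differ")
    if m1.n == 0:
        raise EmptyRegionError("cannot redigitize an empty lesion")
    inside = vol.data[m1.data]
    vmin, vmax = float(inside.min()), float(inside.max())
    if vmax <= vmin:
        raise DegenerateLesionError(f"lesion intensity range is zero (SUV {vmin})")
    bins = np.zeros(vol.shape, dtype=np.int16)
    scaled = (vol.data[m1.data] - vmin) / (vmax - vmin) * (N_BINS - 1)
    bins[m1.data] = np.floor(scaled + 0.5).astype(np.int16)
    return RedigitizedVolume(bins, source_min=vmin, source_max=vmax)


def intensity_weighted_gradient(
    redig: RedigitizedVolume, vol: SUVVolume, m1: VOIMask
) -> GradientVolume:
    """Gradient magnitude of the binned image, weighted by SUV.

    Central differences in voxel units on the binned grid; voxels outside
    the grid (and outside M1, where bins are already zero) contribute 0.
    The result is zeroed outside M1.
    """
    if redig.data.shape != vol.shape or m1.shape != vol.shape:
        raise ValueError("shape mismatch between bins, volume, and mask")
    padded = np.pad(redig.data.astype(np.float64), 1, mode="constant")
    c = (slice(1, -1),)
    gz = (padded[2:, 1:-1, 1:-1] - padded[:-2, 1:-1, 1:-1]) / 2.0
    gy = (padded[1:-1, 2:, 1:-1] - padded[1:-1, :-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 1:-1, 2:] - padded[1:-1, 1:-1, :-2]) / 2.0
    magnitude = np.sqrt(gz**2 + gy**2 + gx**2)
    g = magnitude * vol.data
    g[~m1.data] = 0.0
    return GradientVolume(g, stage="raw")


def smooth_then_erode(g: GradientVolume) -> GradientVolume:
    """3x3x3 mean filter (zero-padded), then one 3x3x3 grayscale erosion.

    The erosion takes the local minimum; outside-grid neighbours are
    treated as +inf so the border behaves as a no-op.  Smoothing spreads
    and damps noise spikes; the erosion then removes thin bright ridges —
    in particular the one-voxel rind of spurious gradient at the VOI
    boundary, which would otherwise wall off the region growing.
    """
    if g.stage != "raw":
        raise ValueError(f"expected a raw gradient image, got stage {g.stage!r}")
    smoothed = ndi.uniform_filter(g.data, size=3, mode="constant", cval=0.0)
    eroded = ndi.minimum_filter(smoothed, size=3, mode="constant", cval=np.inf)
    return GradientVolume(np.maximum(eroded, 0.0), stage="eroded")


def find_seed(g: GradientVolume, search_mask: VOIMask) -> tuple[int, int, int]:
    """Coordinate of the minimal gradient value within the search mask.

    Ties are broken by lexicographic (z, y, x) order.
    """
    if search_mask.shape != g.data.shape:
        raise ValueError("mask and gradient shapes differ")
    if search_mask.n == 0:
        raise EmptyRegionError("seed search mask is empty")
    masked = np.where(search_mask.data, g.data, np.inf)
    flat = int(np.argmin(masked))  # C order == lexicographic (z, y, x)
    return tuple(int(c) for c in np.unravel_index(flat, g.data.shape))


def grow_necrotic_core(
    g: GradientVolume,
    seed: tuple[int, int, int],
    m1: VOIMask,
    growth_factor: float = 3.0,
) -> VOIMask:
    """Region-grow the necrotic core from the seed voxel.

    The core is the 6-connected component, within M1, of voxels whose
    gradient value is <= growth_factor * g(seed) (inclusive), containing
    the seed.  It therefore always contains the seed, and with a seed
    value of exactly 0 it is the 6-connected zero plateau.
    """
    seed = tuple(int(c) for c in seed)
    if not m1.data[seed]:
        raise ValueError(f"seed {seed} lies outside the lesion mask")
    threshold = growth_factor * float(g.data[seed])
    candidate = (g.data <= threshold) & m1.data
    labels, _ = ndi.label(candidate, structure=STRUCT_6)
    return VOIMask(labels == labels[seed], role="necrotic_core")


def _mean_bins(redig: RedigitizedVolume, voi: VOIMask, what: str) -> float:
    if voi.shape != redig.data.shape:
        raise ValueError("mask and bin-image shapes differ")
    if voi.n == 0:
        raise EmptyRegionError(f"empty {what} VOI")
    return float(redig.data[voi.data].mean())


def core_metabolism(redig: RedigitizedVolume, core: VOIMask) -> float:
    """Mean redigitized intensity over the necrotic core VOI (in [0, 15])."""
    return _mean_bins(redig, core, "necrotic core")


def surface_metabolism(redig: RedigitizedVolume, surface: VOIMask) -> float:
    """Mean redigitized intensity over the surface tumor VOI (in [0, 15])."""
    return _mean_bins(redig, surface, "surface tumor")


def shell_thickness(n: int) -> int:
    """Surface-shell thickness k = n^(1/3) * 0.1, rounded, clamped to >= 1.

    n is the lesion voxel count; the cube root makes k proportional to the
    VOI's linear size.  Rounding is half away from zero, and the result is
    clamped to at least one voxel so the surface shell is never empty by
    construction.
    """
    if n < 1:
        raise EmptyRegionError("lesion has no voxels")
    return max(1, round_half_up(n ** (1.0 / 3.0) * 0.1))


def surface_voi(m1: VOIMask, k: int) -> tuple[VOIMask, VOIMask]:
    """Surface shell and eroded mask: M2 = erode^k(M1), surface = M1 \\ M2.

    The erosion uses the same 3x3x3 kernel as the rest of the pipeline.
    If k erosions exhaust the lesion, M2 is empty, the surface equals M1,
    and a warning is raised.
    """
    if m1.n == 0:
        raise EmptyRegionError("cannot erode an empty lesion mask")
    if k < 1:
        raise ValueError(f"shell thickness k must be >= 1, got {k}")
    m2 = ndi.binary_erosion(m1.data, structure=STRUCT_26, iterations=k, border_value=0)
    if not m2.any():
        warnings.warn(
            f"{k} erosions exhausted the lesion mask; surface VOI equals the whole lesion",
            RuntimeWarning,
            stacklevel=2,
        )
    surface = m1.data & ~m2
    return VOIMask(surface, role="surface"), VOIMask(m2, role="eroded_lesion")


def compute_ratio(
    vol: SUVVolume,
    approx_point: tuple[int, int, int],
    *,
    suv_threshold: float = 2.5,
    growth_factor: float = 3.0,
    fill_holes: bool = True,
    max_seed_distance: float = 20.0,
) -> TNRResult:
    """Run the full metabolic tumor/necrosis ratio pipeline on one volume.

    Raises
    ------
    NoLesionError, SeedMismatchError, DegenerateLesionError, EmptyRegionError
        Propagated from the individual stages.
    UndefinedRatioError
        If the necrotic core metabolism is exactly zero; the exception
        carries the partial result for inspection.
    """
    m1 = segment_lesion(
        vol,
        approx_point,
        threshold=suv_threshold,
        fill_holes=fill_holes,
        max_seed_distance=max_seed_distance,
    )
    redig = redigitize(vol, m1)
    g = smooth_then_erode(intensity_weighted_gradient(redig, vol, m1))

    # Exclude the one-voxel boundary layer from seeding; boundary voxels sit
    # on the lesion/background rind where the gradient image is artefactual.
    eroded_once = ndi.binary_erosion(m1.data, structure=STRUCT_26, border_value=0)
    if eroded_once.any():
        search = VOIMask(eroded_once, role="eroded_lesion")
    else:
        warnings.warn(
            "lesion too small to erode; seed search uses the full lesion mask",
            RuntimeWarning,
            stacklevel=2,
        )
        search = m1
    seed = find_seed(g, search)

    core = grow_necrotic_core(g, seed, m1, growth_factor=growth_factor)
    n = m1.n
    k = shell_thickness(n)
    surface, m2 = surface_voi(m1, k)

    core_met = core_metabolism(redig, core)
    surf_met = surface_metabolism(redig, surface)
    overlap = float((core.data & surface.data).sum()) / core.n

    partial = dict(
        seed=seed, k=k, n=n, core_metabolism=core_met, surface_metabolism=surf_met
    )
    if core_met == 0.0:
        raise UndefinedRatioError(
            "necrotic core metabolism is zero; ratio undefined", partial=partial
        )

    return TNRResult(
        ratio=surf_met / core_met,
        surface_metabolism=surf_met,
        core_metabolism=core_met,
        k=k,
        n=n,
        seed=seed,
        suv_max=suv_max(vol, m1),
        lesion_voi=m1,
        m2_voi=m2,
        surface_voi=surface,
        core_voi=core,
        core_surface_overlap=overlap,
        suv_threshold=suv_threshold,
        growth_factor=growth_factor,
    )
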
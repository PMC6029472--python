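"""Seeded digital PET phantoms of uterine smooth-muscle tumors.

Clinical raw images for the method's original cohort are unrecoverable, so
every pipeline stage is exercised on synthetic volumes that emulate the
two uptake phenotypes the ratio separates:

* ``hollow_ball`` — malignant phenotype: a metabolically active ellipsoidal
  rim around an abrupt, possibly eccentric photopenic necrotic core
  (coagulative tumor necrosis).
* ``hyaline`` — gradual sigmoid decline from rim to a mildly cooler centre,
  the benign hyaline-degeneration analogue of the hollow ball; as the
  transition width grows the two phenotypes converge.
* ``heterogeneous`` / ``focal`` / ``diffuse_low`` / ``diffuse_high`` —
  the four benign uptake patterns observed in leiomyomas: multiple mild
  uptake blobs, one circumscribed active region inside a quiescent mass,
  and uniform low/high uptake.

Benign lesions additionally receive a mild smooth central reduction of
uptake (quadratic radial profile): large leiomyomas routinely degenerate
centrally, their blood supply entering from the periphery, and this
centripetal decline is what keeps the measured surface and core
metabolisms comparable in benign masses.

Each phantom is blurred with a Gaussian point-spread function (default
FWHM 4.80 mm, the axial resolution of the clinical scanner), then
corrupted with Gaussian noise of standard deviation proportional to the
local mean, and clipped at zero.  Identical seeds give bit-identical
volumes, and the ground-truth masks describe the pre-blur geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidSpecError
from .suv_volume import SUVVolume, VOIMask

PATTERNS = (
    "hollow_ball",
    "hyaline",
    "heterogeneous",
    "focal",
    "diffuse_low",
    "diffuse_high",
)

#: Benign patterns that receive the central-degeneration profile.
_BENIGN = ("heterogeneous", "focal", "diffuse_low", "diffuse_high")

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.355


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of one synthetic lesion.

    All lengths are in mm, all intensities in SUV; arrays and coordinate
    triples follow the package-wide (z, y, x) order.  ``rim_suv`` is the
    active-tissue plateau (for diffuse patterns simply the lesion
    plateau); ``core_suv`` is the necrotic/quiescent level (for ``focal``
    it is the sub-threshold bulk of the mass).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    pattern: str = "hollow_ball"
    tumor_radii: tuple[float, float, float] = (50.0, 45.0, 40.0)
    core_radii: tuple[float, float, float] = (24.0, 22.0, 20.0)
    core_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rim_suv: float = 8.0
    core_suv: float = 1.5
    background_suv: float = 1.0
    transition_width: float = 0.0
    central_dip: float = 0.25
    n_blobs: int = 4
    blob_amplitude_frac: float = 0.10
    tissue_texture_frac: float = 0.15
    necrosis_texture_frac: float = 0.40
    texture_corr_mm: float = 10.0
    noise_sigma_frac: float = 0.05
    noise_floor_suv: float = 4.0
    psf_fwhm: float = 4.80
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise InvalidSpecError(f"unknown pattern {self.pattern!r}; expected {PATTERNS}")
        for name in ("rim_suv", "core_suv", "background_suv"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if any(r <= 0 for r in self.tumor_radii) or any(r <= 0 for r in self.core_radii):
            raise InvalidSpecError("all radii must be positive")
        if self.noise_sigma_frac < 0 or self.psf_fwhm < 0:
            raise InvalidSpecError("noise and PSF parameters must be >= 0")
        if not 0 <= self.central_dip < 1:
            raise InvalidSpecError("central_dip must be in [0, 1)")


@dataclass
class PhantomTruth:
    """A generated phantom with its pre-blur ground-truth geometry."""

    volume: SUVVolume
    tumor_mask: VOIMask
    core_mask: VOIMask
    spec: PhantomSpec


def _coords_mm(spec: PhantomSpec):
    """Physical (z, y, x) coordinate grids, origin at the volume centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_rho(coords, center_mm, radii_mm):
    """Normalised ellipsoidal radius: <=1 inside the ellipsoid."""
    return np.sqrt(
        sum(((c - o) / r) ** 2 for c, o, r in zip(coords, center_mm, radii_mm))
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def generate(spec: PhantomSpec) -> PhantomTruth:
    """Generate one phantom volume with ground-truth masks.

    The noiseless pattern field is built first, then blurred with the PSF,
    then noise with sigma = noise_sigma_frac x local mean is added and the
    result clipped at zero.  The returned masks describe the pre-blur
    geometry and are independent of the noise realisation.
    """
    rng = np.random.default_rng(spec.rng_seed)
    coords = _coords_mm(spec)
    center = (0.0, 0.0, 0.0)
    rho_tumor = _ellipsoid_rho(coords, center, spec.tumor_radii)
    tumor = rho_tumor <= 1.0

    needs_core = spec.pattern in ("hollow_ball", "hyaline", "focal")
    rho_core = _ellipsoid_rho(coords, spec.core_offset, spec.core_radii)
    core = rho_core <= 1.0
    if needs_core:
        if not core.any():
            raise InvalidSpecError("core ellipsoid contains no voxel")
        if np.any(core & ~tumor):
            raise InvalidSpecError("core ellipsoid extends outside the tumor")

    field_ = np.full(spec.grid_shape, spec.background_suv, dtype=np.float64)

    if spec.pattern in ("hollow_ball", "hyaline"):
        field_[tumor] = spec.rim_suv
        if spec.transition_width <= 0:
            field_[core] = spec.core_suv
        else:
            # Signed distance from the core boundary, in mm, scaled so the
            # transition spans roughly transition_width from ~12% to ~88%.
            mean_core_r = float(np.mean(spec.core_radii))
            d_mm = (rho_core - 1.0) * mean_core_r
            blend = _sigmoid(d_mm / (spec.transition_width / 4.0))
            inside = tumor
            field_[inside] = spec.core_suv + (spec.rim_suv - spec.core_suv) * blend[inside]
    elif spec.pattern in ("diffuse_low", "diffuse_high"):
        field_[tumor] = spec.rim_suv
    elif spec.pattern == "heterogeneous":
        field_[tumor] = spec.rim_suv
        bump = np.zeros(spec.grid_shape)
        for _ in range(max(spec.n_blobs, 0)):
            # Blob centres inside 70% of the tumor radius; widths 8-16 mm.
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r_frac = 0.7 * rng.uniform() ** (1 / 3)
            c_mm = [r_frac * ui * ri for ui, ri in zip(u, spec.tumor_radii)]
            width = rng.uniform(8.0, 16.0)
            sign = rng.choice([-1.0, 1.0])
            rho_b = _ellipsoid_rho(coords, c_mm, (width, width, width))
            bump += sign * spec.blob_amplitude_frac * spec.rim_suv * np.exp(-rho_b**2)
        field_[tumor] += bump[tumor]
    elif spec.pattern == "focal":
        field_[tumor] = spec.core_suv  # quiescent bulk of the mass
        width = spec.transition_width if spec.transition_width > 0 else 3.0
        mean_core_r = float(np.mean(spec.core_radii))
        d_mm = (1.0 - rho_core) * mean_core_r  # positive inside the focal region
        blend = _sigmoid(d_mm / (width / 4.0))
        field_[tumor] += (spec.rim_suv - spec.core_suv) * blend[tumor]

    # Smooth multiplicative tissue texture: biological tissue is never
    # mathematically uniform, and a perfectly flat synthetic core would
    # quantize to a single redigitization bin (an exact zero-gradient
    # plateau no clinical image exhibits).  Coagulative necrosis gets a
    # stronger modulation — necrotic cores retain patchy residual signal
    # from debris and hemorrhage.
    def _texture(frac: float) -> np.ndarray:
        from scipy.ndimage import gaussian_filter

        raw = rng.normal(size=spec.grid_shape)
        sig = [spec.texture_corr_mm / s for s in spec.spacing]
        smooth = gaussian_filter(raw, sigma=sig, mode="nearest")
        smooth /= max(smooth.std(), 1e-12)
        return np.exp(frac * smooth - frac**2 / 2.0)  # mean-preserving lognormal

    if spec.tissue_texture_frac > 0:
        tex = _texture(spec.tissue_texture_frac)
        field_[tumor] *= tex[tumor]
    if spec.pattern == "hollow_ball" and spec.necrosis_texture_frac > 0:
        tex = _texture(spec.necrosis_texture_frac)
        field_[core] *= tex[core]

    if spec.pattern in _BENIGN and spec.central_dip > 0:
        # Centripetal degeneration: uptake excess over background shrinks
        # quadratically toward the centre of the active region.
        rho = rho_core if spec.pattern == "focal" else rho_tumor
        dip = 1.0 - spec.central_dip * np.clip(1.0 - rho**2, 0.0, 1.0)
        field_[tumor] = (
            spec.background_suv + (field_[tumor] - spec.background_suv) * dip[tumor]
        )

    if spec.psf_fwhm > 0:
        from scipy.ndimage import gaussian_filter

        sigma_vox = [spec.psf_fwhm * FWHM_TO_SIGMA / s for s in spec.spacing]
        field_ = gaussian_filter(field_, sigma=sigma_vox, mode="nearest")

    if spec.noise_sigma_frac > 0:
        # Reconstructed-PET noise is *relatively* larger in photopenic
        # regions (it tracks overall count density, not local uptake), so
        # the proportional sigma is floored at a reference uptake level.
        sigma = spec.noise_sigma_frac * np.maximum(field_, spec.noise_floor_suv)
        field_ = field_ + rng.normal(size=spec.grid_shape) * sigma
    field_ = np.clip(field_, 0.0, None)

    return PhantomTruth(
        volume=SUVVolume(field_, spacing=spec.spacing),
        tumor_mask=VOIMask(tumor, role="tumor"),
        core_mask=VOIMask(core if needs_core and spec.pattern != "focal" else np.zeros_like(tumor), role="necrotic_core"),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Gross lesion diameters (cm) by pattern, mirroring the study cohort.
COHORT_DIAMETERS_CM: Mapping[str, Sequence[float]] = {
    "hollow_ball": (11.9, 5.5, 17.4, 11.4, 5.8, 8.8, 8.6, 13.7),
    "heterogeneous": (8.8, 5.7, 5.4, 11.6),
    "focal": (6.5, 10.2, 5.0, 16.7),
    "diffuse_low": (14.0, 16.0, 10.2, 7.9),
    "diffuse_high": (11.1,),
}

#: Active-tissue plateau SUV ranges by pattern (low clinical range for the
#: benign patterns; diffuse-low sits just above the 2.5 segmentation cut).
_RIM_SUV_RANGES = {
    "hollow_ball": (4.0, 11.0),
    "hyaline": (3.4, 4.2),
    "heterogeneous": (2.9, 3.6),
    "focal": (3.2, 4.2),
    "diffuse_low": (2.9, 3.4),
    "diffuse_high": (6.0, 8.0),
}


def _spec_for(pattern: str, diameter_cm: float, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """One jittered cohort member of the given pattern and gross size."""
    base = PhantomSpec(pattern=pattern)
    # Cap the radius so the lesion plus a blur margin fits in the grid.
    max_r = 0.42 * min(n * s for n, s in zip(base.grid_shape, base.spacing))
    mean_r = min(diameter_cm * 10.0 / 2.0, max_r)
    aniso = rng.uniform(0.88, 1.12, size=3)
    aniso /= np.prod(aniso) ** (1 / 3)  # normalise geometric mean to 1
    tumor_radii = tuple(float(min(mean_r * a, max_r)) for a in aniso)
    lo, hi = _RIM_SUV_RANGES[pattern]
    rim = float(rng.uniform(lo, hi))

    kwargs: dict = dict(
        pattern=pattern,
        tumor_radii=tumor_radii,
        rim_suv=rim,
        rng_seed=seed,
    )
    if pattern == "hollow_ball":
        frac = rng.uniform(0.38, 0.55)
        core_radii = tuple(float(r * frac) for r in tumor_radii)
        room = np.array(tumor_radii) - np.array(core_radii)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = tuple(float(0.3 * rng.uniform() * rm * d) for rm, d in zip(room, direction))
        kwargs.update(
            core_radii=core_radii,
            core_offset=offset,
            core_suv=float(rng.uniform(1.0, 1.8)),
            transition_width=0.0,
        )
    elif pattern == "hyaline":
        frac = rng.uniform(0.38, 0.55)
        kwargs.update(
            core_radii=tuple(float(r * frac) for r in tumor_radii),
            core_suv=0.8 * rim,
            transition_width=25.0,
        )
    elif pattern == "focal":
        focal_radii = tuple(float(max(0.6 * r, 16.0)) for r in tumor_radii)
        kwargs.update(
            core_radii=tuple(min(fr, tr) for fr, tr in zip(focal_radii, tumor_radii)),
            core_suv=float(rng.uniform(1.4, 1.9)),
            transition_width=3.0,
        )
    return replace(base, **kwargs)


def cohort(counts: Mapping[str, int], seed: int) -> list[PhantomTruth]:
    """Deterministically generate a batch of phantoms, ``counts`` per pattern.

    Gross diameters cycle through the per-pattern clinical values in
    :data:`COHORT_DIAMETERS_CM` with a +/-5% jitter (patterns without a
    listed diameter draw uniformly from 5-16 cm).  All randomness derives
    from ``seed``; the same seed reproduces the same batch.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    out: list[PhantomTruth] = []
    child_seeds = iter(ss.spawn(sum(counts.values()) or 1))
    for pattern in PATTERNS:
        if pattern not in counts:
            continue
        diameters = COHORT_DIAMETERS_CM.get(pattern)
        for i in range(counts[pattern]):
            if diameters:
                d = diameters[i % len(diameters)] * rng.uniform(0.95, 1.05)
            else:
                d = rng.uniform(5.0, 16.0)
            child = int(next(child_seeds).generate_state(1)[0] % (2**31))
            out.append(generate(_spec_for(pattern, d, rng, child)))
    return out


def default_cohort(seed: int) -> list[PhantomTruth]:
    """The 21-lesion synthetic cohort: 8 malignant and 13 benign phantoms.

    Pattern counts mirror the clinical study: 8 hollow-ball, and for the
    benign group 4 heterogeneous, 4 focal, 4 diffuse-low, 1 diffuse-high.
    """
    return cohort(
        {
            "hollow_ball": 8,
            "heterogeneous": 4,
            "focal": 4,
            "diffuse_low": 4,
            "diffuse_high": 1,
        },
        seed,
    )


def is_malignant(truth: PhantomTruth) -> bool:
    """Whether a phantom carries the malignant (hollow-ball) phenotype."""
    return truth.spec.pattern == "hollow_ball"


def operator_point(truth: PhantomTruth) -> tuple[int, int, int]:
    """A realistic operator click: the hottest voxel of the gross tumor.

    Clicking the most FDG-avid part of the mass is how a lesion VOI is
    anchored in practice; in particular it never lands on the photopenic
    necrotic centre, whose interior speckle is not part of the avid rim.
    """
    masked = np.where(truth.tumor_mask.data, truth.volume.data, -np.inf)
    flat = int(np.argmax(masked))
    return tuple(int(c) for c in np.unravel_index(flat, masked.shape))
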
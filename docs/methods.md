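# Methods

## The measurement

The metabolic tumor/necrosis ratio quantifies how sharply a uterine
mass's metabolically active surface contrasts with its interior. Its
premise is histological: coagulative tumor necrosis (a diagnostic
criterion of leiomyosarcoma, and present in STUMP) has an *abrupt*
boundary between dead and viable tumor, which on FDG PET appears as a
photopenic core inside an avid rim; benign hyaline degeneration has a
gradual transition zone and no such edge.

Pipeline, on a volume of SUV values (arrays indexed `(z, y, x)`,
coordinates 0-based; the algorithm operates in voxel units and never
consults physical spacing):

1. **Lesion mask M1.** The 26-connected component of
   `{SUV >= threshold}` (threshold 2.5, inclusive) containing the
   operator's point; a sub-threshold click snaps to the nearest
   supra-threshold voxel (Euclidean distance in voxel units, ties
   lexicographic in `(z, y, x)`, rejection beyond 20 voxels). Cavities
   fully enclosed by the component are then filled (`fill_holes=True`):
   the necrotic core of a hollow-ball lesion is itself sub-threshold, and
   the core segmentation below must operate inside the lesion VOI, so a
   purely supra-threshold mask — a hollow shell — would exclude the very
   tissue the measurement quantifies. With filling, raising the threshold
   still never grows M1 (hole filling is monotone under set inclusion).
2. **Redigitization.** `bin(v) = round_half_up(15 · (v − min)/(max − min))`
   over M1, zero outside. Minimum maps to 0 and maximum to 15 exactly;
   the 16 integer levels realise "16 equally spaced bins". A lesion with
   zero intensity range is rejected (degenerate). Bins are invariant
   under any positive affine rescaling of the SUV volume.
3. **Intensity-weighted gradient (IWG).** Central differences of the
   binned image in voxel units (outside-grid and outside-M1 neighbours
   contribute 0), L2 magnitude, multiplied by the *original SUV* image,
   zeroed outside M1. SUV (not the binned values) is used as the weight:
   the construction contrasts the "redigitized" image with the "original"
   one, and weighting by SUV is what makes a photopenic region's gradient
   noise an order of magnitude smaller than an avid region's — the core
   of the method's discrimination (see "Why benign lesions measure ≈ 1").
4. **Smooth, then erode.** 3×3×3 mean filter (zero padding), then one
   grayscale erosion (3×3×3 minimum filter; outside-grid neighbours act
   as +inf, i.e. the border is a no-op). The erosion is read as acting on
   the *image*, not the mask; it removes thin bright ridges — notably the
   one-voxel rind of spurious gradient where bins fall to 0 at the M1
   boundary, which would otherwise wall off the region growing.
   Additionally, the *seed search* (not the growth) is restricted to M1
   binary-eroded once, so a boundary voxel can never seed the core. Both
   protections are deliberate and documented here because the narrated
   procedure is ambiguous about which object "eroded once" applies to.
5. **Necrotic core VOI.** From the minimum of the processed IWG image
   (ties lexicographic), 6-connected region growing within all of M1 at
   inclusive threshold `3 × IWG(seed)`. 6-connectivity keeps the core
   conservative; growth is allowed back into the boundary layer because a
   genuinely eccentric core may touch it (the overlap fraction between
   core and surface shell is reported as a diagnostic).
6. **Surface VOI.** `k = max(1, round_half_away_from_zero(n^(1/3) · 0.1))`
   with `n = |M1|`; M2 is M1 binary-eroded `k` times with the same 3×3×3
   element; surface = M1 \ M2. The clamp to `k >= 1` keeps the shell
   nonempty by construction; if `k` erosions exhaust the lesion the
   surface equals M1 and a warning is raised.
7. **Ratio.** Mean bin over surface / mean bin over core, both in
   [0, 15], reported at full precision (displayed to 3 decimals, matching
   the reference table). A core metabolism of exactly zero raises an
   explicit undefined-ratio error carrying all intermediates — never a
   silent infinity.

### Why benign lesions measure ≈ 1

In a lesion without an abrupt internal edge the binned image is
dominated by noise and mild texture, so the IWG field has no barrier
anywhere near 3× its own minimum: the growing floods essentially the
whole VOI and the denominator becomes the lesion-wide mean bin, close to
the shell's mean. In a hollow-ball lesion the seed lands in the cold,
flat core, where the intensity weighting makes the IWG tiny; tripling it
cannot cross the steep rim interface, the core VOI stays confined to the
necrotic centre whose bins sit near 0, and the ratio grows several-fold.

## SUV handling and I/O

`SUV = activity (Bq/mL) / (injected activity (Bq) / (body weight (kg) × 1000))`.
Volumes already in SUV need no metadata; values are never rescaled or
clamped on load. NIfTI-1 is the on-disk format (arrays transposed to the
`(x, y, z)` layout nibabel expects); masks are unsigned 8-bit 0/1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `suv_threshold` | 2.5 | inclusive lesion-membership cut (SUV) |
| `growth_factor` | 3.0 | region-growing threshold multiplier on the seed IWG |
| `fill_holes` | true | include enclosed photopenic cavities in M1 |
| `max_seed_distance` | 20 voxels | operator-click snap limit |
| bins | 16 (0–15) | fixed by the method |
| `ratio_cutoff` | 1.25 | malignancy call on the ratio; any value in the open interval between the largest benign (1.069) and smallest malignant (1.421) reference value reproduces the reference classification |
| `suvmax_cutoff` | 4.5 | ROC-derived SUVmax cutoff of the reference study, taken as a given parameter (Youden on the printed values would prefer a lower cutoff with higher J — the study's SPSS criterion is not recoverable) |

Classifier calls are strictly greater-than; no reference score equals a
cutoff, so reproduction is unambiguous.

## The synthetic cohort

No raw clinical images exist any more for the reference cohort, so the
pipeline is validated on digital phantoms (`tnrpet.phantom`). Each
phantom is an ellipsoidal lesion on a soft-tissue background (SUV 1.0)
on a 64³ grid of 4 mm isotropic voxels (the study never states the PET
voxel size; 4 mm is a typical whole-body value and configurable),
blurred with a Gaussian PSF of FWHM 4.80 mm (the reference scanner's
axial resolution), with Gaussian voxel noise and clipping at zero.

Phenotypes:

* `hollow_ball` (malignant): avid rim (plateau SUV 4–11 across the
  cohort) around an abrupt, possibly eccentric necrotic core (SUV
  1.0–1.8 before texture).
* `hyaline`: same geometry with a wide sigmoid rim→core transition and a
  shallow dip — the benign degeneration analogue. As the transition
  width grows past the PSF scale, the measured ratio collapses from the
  malignant range toward the benign one (tested on widths 0→50 mm).
* `heterogeneous`, `focal`, `diffuse_low`, `diffuse_high` (benign): mild
  uptake blobs, a circumscribed PSF-limited active region inside a
  quiescent mass, and uniform low/high plateaus.

Realism choices that matter, and why:

* **Tissue texture.** Uptake is modulated by a smooth mean-preserving
  lognormal field (15% lesion-wide; 40% inside coagulative cores, whose
  debris and hemorrhage retain patchy signal). Mathematically uniform
  tissue would quantize to a single bin, producing exact zero-gradient
  plateaus and 0/0 ratios that no clinical image exhibits — and it is
  this residual core signal that keeps malignant core metabolisms
  nonzero, as in the reference data (malignant ratios there: 1.4–5.5).
* **Noise.** σ = 5% of the local mean, floored at 5% of SUV 4.0:
  reconstructed-PET noise tracks overall count density, so *relative*
  noise rises in photopenic regions; a purely proportional model would
  make necrotic cores nearly noiseless.
* **Central degeneration.** Benign lesions get a smooth quadratic
  centripetal reduction of uptake excess (25% at the centre): large
  leiomyomas are supplied from the periphery and degenerate centrally.
  This mild, gradual dip is what keeps benign surface and core
  metabolisms comparable.
* **Benign plateau levels** are anchored to the SUVmax of the reference
  benign cases whose ratios were actually measured (≈3–4); diffuse-low
  plateaus sit just above the 2.5 threshold because a sub-threshold
  lesion yields no mask at all (several clinical diffuse-low cases were
  indeed unmeasurable).
* **Geometry** mirrors the reference cohort's printed per-pattern gross
  diameters (5.0–17.4 cm) with ±5% jitter and mild anisotropy.
* **Operator point.** Batch evaluation clicks the hottest gross-tumor
  voxel, as an operator anchoring a VOI on the avid rim would; the
  volume centre of a hollow-ball lesion is photopenic and would snap
  onto interior speckle.

What the phantoms do **not** model: sinogram-level physics (attenuation,
scatter, reconstruction artifacts), adjacent FDG-avid organs (bladder),
respiratory/organ motion, partial-volume recovery corrections, and
correlated reconstruction noise. Passing the synthetic-cohort tests
therefore shows the algorithm separates the two *phenotypes as modelled*;
it does not re-derive the clinical ratio values, and synthetic malignant
ratios (≈2–12) run higher than the published ones because synthetic
cores are cleaner than reconstructed clinical PET.

On the default 21-phantom cohort (8 hollow-ball, 13 benign, batch seed
7) the groups separate completely, benign ratios stay within
[0.85, 1.15] and malignant ones above 1.4. Across other batch seeds the
smallest focal lesions can measure as low as ≈0.84: with `k = 1` their
surface shell is exactly the partial-volume layer, the coldest part of a
small benign mass. The full cohort runs in well under a minute on one
CPU (≈0.3 s per phantom).

## Cohort statistics

The packaged 21-patient table (8 LMS/STUMP, 13 leiomyomas, 7 ratios
missing because the raw images were lost) is checksummed on load. From
it the module regenerates the study's statistics:

* **Mann–Whitney U**: mid-ranks for ties; the exact two-tailed p is a
  full enumeration over all group labelings whenever n ≤ 25 (the
  permutation distribution of U is symmetric about n₁n₂/2), with the
  tie-corrected normal approximation (no continuity correction) always
  reported alongside. On SUVmax the two give 0.0024 and 0.0037,
  bracketing the published 0.003 (whether that value was exact or
  asymptotic is not recoverable, hence both).
* **Pearson r** with a t-distribution p on n−2 df (malignant SUVmax vs
  mitotic count: r = 0.840, p = 0.009, n = 8).
* **Exact McNemar**: `p = min(1, 2·P(Bin(b+c, ½) ≤ min(b, c)))`; the 5
  SUVmax errors vs 0 sign errors give 0.0625 (printed as 0.063).
* **ROC/Youden** over all midpoints between adjacent distinct scores,
  ties taking the lowest cutoff.
* Percentages are rounded half-up to integers (table formatting); raw
  fractions are always carried alongside, and zero-denominator metrics
  are flagged undefined rather than raised.

A documented inconsistency in the source tables is preserved rather than
reconciled: the per-group summary lists the benign size range as
4.5–16.7 cm while the per-patient minimum is 5.0 cm; the fixture stores
the per-patient values verbatim, so ranges computed here start at 5.0.

## Known limitations

* The absolute clinical ratio values cannot be reproduced from images
  (no images survive); the image pipeline is validated by oracle
  equivalence, invariants, and phenotype separation only.
* Single-lesion workflow; no multi-lesion batch detection, no guard
  against a VOI leaking into adjacent avid organs beyond an optional
  bounding box at segmentation time.
* A lesion entirely below SUV 2.5 (as several clinical diffuse-low
  leiomyomas were) has no VOI and no ratio, by construction.
* `k = 1` shells on very small lesions are dominated by the
  partial-volume layer, biasing benign ratios slightly below 1.
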
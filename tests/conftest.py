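import numpy as np
import pytest

from tnrpet import cohort_stats as cs
from tnrpet import phantom as ph


@pytest.fixture(scope="session")
def records():
    return cs.load_cohort()


@pytest.fixture(scope="session")
def malignant(records):
    return [r for r in records if r.diagnosis_class == "malignant"]


@pytest.fixture(scope="session")
def benign(records):
    return [r for r in records if r.diagnosis_class == "benign"]


@pytest.fixture(scope="session")
def hollow_ball_truth():
    """A default malignant phantom shared by the slower end-to-end tests."""
    return ph.generate(ph.PhantomSpec(rng_seed=42))


# ---------------------------------------------------------------------------
# Brute-force oracles, deliberately independent of the implementation
# ---------------------------------------------------------------------------


def flood_fill_6(candidate: np.ndarray, seed: tuple) -> np.ndarray:
    """Breadth-first 6-connected flood fill over a boolean candidate mask."""
    out = np.zeros_like(candidate, dtype=bool)
    if not candidate[seed]:
        return out
    stack = [tuple(seed)]
    out[tuple(seed)] = True
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if (
                0 <= nz < candidate.shape[0]
                and 0 <= ny < candidate.shape[1]
                and 0 <= nx < candidate.shape[2]
                and candidate[nz, ny, nx]
                and not out[nz, ny, nx]
            ):
                out[nz, ny, nx] = True
                stack.append((nz, ny, nx))
    return out


def connected_component_26(mask: np.ndarray, seed: tuple) -> np.ndarray:
    """Breadth-first 26-connected component of a boolean mask."""
    out = np.zeros_like(mask, dtype=bool)
    if not mask[seed]:
        return out
    stack = [tuple(seed)]
    out[tuple(seed)] = True
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (
                0 <= nz < mask.shape[0]
                and 0 <= ny < mask.shape[1]
                and 0 <= nx < mask.shape[2]
                and mask[nz, ny, nx]
                and not out[nz, ny, nx]
            ):
                out[nz, ny, nx] = True
                stack.append((nz, ny, nx))
    return out


def gradient_magnitude_oracle(bins: np.ndarray, suv: np.ndarray, m1: np.ndarray) -> np.ndarray:
    """Per-voxel central differences by explicit loops, zero outside the grid."""
    b = bins.astype(float)

    def at(z, y, x):
        if 0 <= z < b.shape[0] and 0 <= y < b.shape[1] and 0 <= x < b.shape[2]:
            return b[z, y, x]
        return 0.0

    g = np.zeros_like(b)
    for z in range(b.shape[0]):
        for y in range(b.shape[1]):
            for x in range(b.shape[2]):
                gz = (at(z + 1, y, x) - at(z - 1, y, x)) / 2.0
                gy = (at(z, y + 1, x) - at(z, y - 1, x)) / 2.0
                gx = (at(z, y, x + 1) - at(z, y, x - 1)) / 2.0
                g[z, y, x] = np.sqrt(gz**2 + gy**2 + gx**2) * suv[z, y, x]
    g[~m1] = 0.0
    return g
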
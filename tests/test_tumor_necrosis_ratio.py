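import warnings

import numpy as np
import pytest

from tnrpet import (
    GradientVolume,
    SUVVolume,
    VOIMask,
    compute_ratio,
    core_metabolism,
    find_seed,
    grow_necrotic_core,
    intensity_weighted_gradient,
    redigitize,
    shell_thickness,
    smooth_then_erode,
    surface_metabolism,
    surface_voi,
)
from tnrpet import phantom as ph
from tnrpet.errors import DegenerateLesionError, EmptyRegionError
from tnrpet.tumor_necrosis_ratio import STRUCT_6

from conftest import flood_fill_6, gradient_magnitude_oracle


def _full_mask(shape):
    return VOIMask(np.ones(shape, dtype=bool), role="lesion")


# ---------------------------------------------------------------------------
# Redigitization
# ---------------------------------------------------------------------------


def test_redigitize_maps_min_to_zero_and_max_to_fifteen():
    data = np.zeros((1, 1, 3))
    data[0, 0] = [2.5, 5.0, 7.5]
    bins = redigitize(SUVVolume(data), _full_mask(data.shape))
    assert bins.data[0, 0].tolist() == [0, 8, 15]  # midpoint 7.5 rounds up
    assert bins.source_min == 2.5 and bins.source_max == 7.5

    rng = np.random.default_rng(4)
    vol = SUVVolume(rng.uniform(1, 9, size=(6, 6, 6)))
    out = redigitize(vol, _full_mask(vol.shape))
    assert out.data[np.unravel_index(vol.data.argmin(), vol.shape)] == 0
    assert out.data[np.unravel_index(vol.data.argmax(), vol.shape)] == 15
    assert out.data.min() >= 0 and out.data.max() == 15


def test_redigitize_zero_outside_lesion_and_degenerate_error():
    data = np.full((4, 4, 4), 3.0)
    data[0, 0, 0] = 9.0
    mask = np.zeros_like(data, dtype=bool)
    mask[:2] = True
    out = redigitize(SUVVolume(data), VOIMask(mask, role="lesion"))
    assert np.all(out.data[~mask] == 0)
    with pytest.raises(DegenerateLesionError):
        redigitize(SUVVolume(np.full((3, 3, 3), 4.0)), _full_mask((3, 3, 3)))


def test_redigitized_bins_invariant_under_positive_affine_rescaling():
    rng = np.random.default_rng(5)
    data = rng.uniform(1, 10, size=(7, 7, 7))
    mask = VOIMask(rng.random((7, 7, 7)) > 0.3, role="lesion")
    base = redigitize(SUVVolume(data), mask)
    for a, b in ((2.0, 0.0), (0.5, 3.0), (7.3, 1.1)):
        rescaled = redigitize(SUVVolume(a * data + b), mask)
        np.testing.assert_array_equal(rescaled.data, base.data)


# ---------------------------------------------------------------------------
# Intensity-weighted gradient
# ---------------------------------------------------------------------------


def test_gradient_zero_in_constant_interior():
    data = np.full((5, 5, 5), 4.0)
    bins_vol = SUVVolume(data)
    mask = _full_mask(data.shape)
    bins = redigitize(SUVVolume(np.pad(np.full((3, 3, 3), 5.0), 1, constant_values=4.0)), mask)
    g = intensity_weighted_gradient(bins, bins_vol, mask)
    # interior of a constant-bin region: all 27 neighbours share the bin
    assert g.data[2, 2, 2] == 0.0
    assert g.stage == "raw"
    assert np.all(g.data >= 0)


def test_gradient_of_unit_ramp_times_suv():
    # bins ..., 6, 7, 8, ... along x at constant SUV 4 -> |grad| 1, IWG 4
    from tnrpet.tumor_necrosis_ratio import RedigitizedVolume

    bins = np.tile(np.arange(9, dtype=np.int16), (9, 9, 1))
    redig = RedigitizedVolume(bins, 0.0, 8.0)
    vol = SUVVolume(np.full((9, 9, 9), 4.0))
    g = intensity_weighted_gradient(redig, vol, _full_mask((9, 9, 9)))
    assert g.data[4, 4, 4] == pytest.approx(4.0)


@pytest.mark.parametrize("case_seed", range(4))
def test_gradient_matches_bruteforce_oracle(case_seed):
    rng = np.random.default_rng(case_seed)
    shape = (5, 5, 5)
    m1 = rng.random(shape) > 0.25
    suv = rng.uniform(0, 8, size=shape)
    vol = SUVVolume(suv)
    mask = VOIMask(m1, role="lesion")
    if not m1.any():
        pytest.skip("degenerate draw")
    redig = redigitize(vol, mask)
    g = intensity_weighted_gradient(redig, vol, mask)
    oracle = gradient_magnitude_oracle(redig.data, suv, m1)
    np.testing.assert_allclose(g.data, oracle, atol=1e-12)


# ---------------------------------------------------------------------------
# Smoothing and grayscale erosion
# ---------------------------------------------------------------------------


def test_smooth_then_erode_constant_interior_and_bound():
    g = GradientVolume(np.full((7, 7, 7), 3.0), stage="raw")
    out = smooth_then_erode(g)
    assert out.stage == "eroded"
    # interior voxels never see the zero-padded border through mean or min
    assert out.data[3, 3, 3] == pytest.approx(3.0)

    rng = np.random.default_rng(6)
    noisy = GradientVolume(rng.uniform(0, 5, size=(7, 7, 7)), stage="raw")
    from scipy.ndimage import uniform_filter

    smoothed = uniform_filter(noisy.data, size=3, mode="constant", cval=0.0)
    eroded = smooth_then_erode(noisy).data
    assert np.all(eroded <= smoothed + 1e-12)
    assert np.all(eroded >= 0)


def test_single_spike_spreads_then_collapses():
    field = np.zeros((7, 7, 7))
    field[3, 3, 3] = 27.0
    out = smooth_then_erode(GradientVolume(field, stage="raw"))
    # after the mean filter the spike becomes a 3x3x3 plateau of value 1;
    # the minimum filter then keeps only the single centre voxel at 1.
    expected = np.zeros((7, 7, 7))
    expected[3, 3, 3] = 1.0
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Seed search and region growing
# ---------------------------------------------------------------------------


def test_find_seed_unique_minimum_and_tie_break():
    g = np.full((6, 6, 6), 5.0)
    g[3, 4, 5] = 0.5
    grad = GradientVolume(g, stage="eroded")
    assert find_seed(grad, _full_mask(g.shape)) == (3, 4, 5)

    g2 = np.full((4, 4, 4), 5.0)
    g2[1, 1, 1] = 1.0
    g2[2, 0, 0] = 1.0
    assert find_seed(GradientVolume(g2, stage="eroded"), _full_mask(g2.shape)) == (1, 1, 1)

    with pytest.raises(EmptyRegionError):
        find_seed(grad, VOIMask(np.zeros_like(g, dtype=bool)))


def test_grow_core_zero_seed_is_zero_plateau():
    g = np.ones((6, 6, 6))
    g[2:4, 2:4, 2:4] = 0.0
    g[0, 0, 0] = 0.0  # disconnected zero voxel must not join
    core = grow_necrotic_core(GradientVolume(g, stage="eroded"), (2, 2, 2), _full_mask(g.shape))
    expected = np.zeros_like(g, dtype=bool)
    expected[2:4, 2:4, 2:4] = True
    np.testing.assert_array_equal(core.data, expected)


def test_grow_core_uniform_gradient_floods_whole_lesion():
    g = GradientVolume(np.full((5, 5, 5), 2.0), stage="eroded")
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[1:4, 1:4, 1:4] = True
    core = grow_necrotic_core(g, (2, 2, 2), VOIMask(mask, role="lesion"))
    np.testing.assert_array_equal(core.data, mask)


@pytest.mark.parametrize("case_seed", range(6))
def test_grow_core_matches_bruteforce_flood_fill(case_seed):
    rng = np.random.default_rng(100 + case_seed)
    shape = (8, 8, 8)
    g = rng.integers(0, 4, size=shape).astype(float)
    m1 = rng.random(shape) > 0.2
    seeds = np.argwhere(m1)
    seed = tuple(seeds[rng.integers(len(seeds))])
    grad = GradientVolume(g, stage="eroded")
    core = grow_necrotic_core(grad, seed, VOIMask(m1, role="lesion"))
    candidate = (g <= 3.0 * g[seed]) & m1
    np.testing.assert_array_equal(core.data, flood_fill_6(candidate, seed))
    assert core.data[seed]


def test_grow_core_rejects_seed_outside_lesion():
    g = GradientVolume(np.ones((4, 4, 4)), stage="eroded")
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = True
    with pytest.raises(ValueError):
        grow_necrotic_core(g, (3, 3, 3), VOIMask(mask, role="lesion"))


# ---------------------------------------------------------------------------
# Shell thickness and surface VOI
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, expected_k", [(1000, 1), (8000, 2), (125, 1), (27, 1), (1, 1), (125000, 5)])
def test_shell_thickness(n, expected_k):
    assert shell_thickness(n) == expected_k


def test_shell_thickness_requires_voxels():
    with pytest.raises(EmptyRegionError):
        shell_thickness(0)


def test_surface_voi_cube_erosion():
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[2:7, 2:7, 2:7] = True  # solid 5x5x5 cube
    surface, m2 = surface_voi(VOIMask(mask, role="lesion"), 1)
    assert m2.n == 27 and surface.n == 125 - 27
    assert not np.any(surface.data & m2.data)
    np.testing.assert_array_equal(surface.data | m2.data, mask)

    small = np.zeros((5, 5, 5), dtype=bool)
    small[1:4, 1:4, 1:4] = True
    surface, m2 = surface_voi(VOIMask(small, role="lesion"), 1)
    assert m2.n == 1 and surface.n == 26


def test_exhaustive_erosion_warns_and_returns_whole_lesion():
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[2:4, 2:4, 2:4] = True
    with pytest.warns(RuntimeWarning):
        surface, m2 = surface_voi(VOIMask(mask, role="lesion"), 5)
    assert m2.n == 0
    np.testing.assert_array_equal(surface.data, mask)


@pytest.mark.parametrize("case_seed", range(3))
def test_surface_set_algebra_on_random_masks(case_seed):
    rng = np.random.default_rng(200 + case_seed)
    mask = rng.random((10, 10, 10)) > 0.4
    voi = VOIMask(mask, role="lesion")
    for k in (1, 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            surface, m2 = surface_voi(voi, k)
        assert not np.any(surface.data & m2.data)
        np.testing.assert_array_equal(surface.data | m2.data, mask)


# ---------------------------------------------------------------------------
# Metabolisms and the full pipeline
# ---------------------------------------------------------------------------


def test_metabolism_means():
    from tnrpet.tumor_necrosis_ratio import RedigitizedVolume

    bins = np.zeros((3, 3, 3), dtype=np.int16)
    bins[0, 0, :] = [1, 1, 1]
    redig = RedigitizedVolume(bins, 0.0, 1.0)
    voi = np.zeros((3, 3, 3), dtype=bool)
    voi[0, 0, :] = True
    assert core_metabolism(redig, VOIMask(voi, role="necrotic_core")) == 1.0
    single = np.zeros((3, 3, 3), dtype=bool)
    single[2, 2, 2] = True
    assert core_metabolism(redig, VOIMask(single, role="necrotic_core")) == 0.0
    bins15 = np.full((3, 3, 3), 15, dtype=np.int16)
    assert surface_metabolism(RedigitizedVolume(bins15, 0.0, 1.0), VOIMask(voi, role="surface")) == 15.0
    with pytest.raises(EmptyRegionError):
        core_metabolism(redig, VOIMask(np.zeros((3, 3, 3), dtype=bool)))


def test_hollow_ball_pipeline_intermediates(hollow_ball_truth):
    truth = hollow_ball_truth
    result = compute_ratio(truth.volume, ph.operator_point(truth))
    # the seed must land in the true necrotic core, and the core must be
    # markedly colder than the surface shell
    assert truth.core_mask.data[result.seed]
    assert result.core_metabolism < result.surface_metabolism
    assert result.ratio > 1.4
    # set algebra of the audit masks
    assert not np.any(result.surface_voi.data & result.m2_voi.data)
    np.testing.assert_array_equal(
        result.surface_voi.data | result.m2_voi.data, result.lesion_voi.data
    )
    assert np.all(result.lesion_voi.data[result.core_voi.data])
    assert result.n == result.lesion_voi.n
    assert result.k == shell_thickness(result.n)


def test_homogeneous_noisy_lesion_ratio_near_unity():
    spec = ph.PhantomSpec(
        pattern="diffuse_high",
        rim_suv=4.0,
        central_dip=0.0,
        tissue_texture_frac=0.0,
        noise_sigma_frac=0.05,
        rng_seed=42,
    )
    truth = ph.generate(spec)
    result = compute_ratio(truth.volume, ph.operator_point(truth))
    assert 0.85 <= result.ratio <= 1.15


def test_seed_lands_in_eccentric_cores():
    hits = 0
    for i in range(20):
        spec = ph.PhantomSpec(core_offset=(8.0, 6.0, -10.0), rng_seed=300 + i)
        truth = ph.generate(spec)
        result = compute_ratio(truth.volume, ph.operator_point(truth))
        hits += bool(truth.core_mask.data[result.seed])
    assert hits >= 19  # >= 95% of replicates
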
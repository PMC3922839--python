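import itertools

import numpy as np
import pytest

from octovario import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    UnitBlockSet,
    average_variograms,
    common_grid,
    dmax_pixels,
    empirical_variogram,
    fit_power_law,
    gaussian_random_field,
    pair_count,
)
from conftest import brute_force_variogram


def block_set(centroids, values):
    centroids = np.asarray(centroids, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    return UnitBlockSet(
        centroids=centroids[order],
        mean_hu=values[order],
        source_size=np.full(len(values), 8, dtype=np.int64),
    )


def random_block_set(rng, n):
    """n distinct sites on the 8-spaced centroid lattice with random means."""
    lattice = np.array(list(itertools.product(range(8), repeat=3))) * 8.0 + 3.5
    idx = rng.choice(len(lattice), size=n, replace=False)
    return block_set(lattice[idx], rng.normal(-550, 60, n))


class TestPairCount:
    def test_small_values(self):
        assert pair_count(1) == 0
        assert pair_count(2) == 1

    def test_matches_pair_enumeration_at_study_scale(self):
        # 1078 blocks, as a realistic single-subject block count
        n = 1078
        enumerated = sum(1 for _ in itertools.combinations(range(n), 2))
        assert pair_count(n) == enumerated == 580503

    def test_validation(self):
        with pytest.raises(ParameterError):
            pair_count(0)


class TestDmaxPixels:
    def test_mm_to_voxels_truncates_then_rounds_up_to_unit(self):
        assert dmax_pixels(8.0, 0.15, unit_vox=1) == 53
        assert dmax_pixels(8.0, 0.15, unit_vox=8) == 56

    def test_idempotent_on_unit_multiples(self):
        assert dmax_pixels(56 * 0.15, 0.15, unit_vox=8) == 56

    def test_validation(self):
        with pytest.raises(ParameterError):
            dmax_pixels(0, 0.15)
        with pytest.raises(ParameterError):
            dmax_pixels(8, -1)


class TestEmpiricalVariogram:
    def test_two_blocks_direct_substitution(self):
        blocks = block_set([[3.5, 3.5, 3.5], [11.5, 3.5, 3.5]], [100.0, 200.0])
        v = empirical_variogram(blocks, d_max_vox=56)
        assert v.distances.tolist() == [8.0]
        assert v.pair_counts.tolist() == [1]
        assert v.gamma[0] == pytest.approx((100 - 200) ** 2 / 2)

    def test_constant_field_gives_zero_gamma(self, rng):
        blocks = random_block_set(rng, 30)
        blocks.mean_hu[:] = -500.0
        v = empirical_variogram(blocks, d_max_vox=100)
        assert np.all(v.gamma == 0)

    @pytest.mark.parametrize("n", [5, 20, 60])
    def test_matches_brute_force_oracle(self, rng, n):
        blocks = random_block_set(rng, n)
        v = empirical_variogram(blocks, d_max_vox=1000)
        dists, gamma, counts = brute_force_variogram(blocks.centroids, blocks.mean_hu)
        assert np.allclose(v.distances, dists)
        assert np.allclose(v.gamma, gamma, rtol=1e-10)
        assert np.array_equal(v.pair_counts, counts)
        assert int(v.full_pair_counts.sum()) == pair_count(n)

    def test_truncation_keeps_full_curve(self, rng):
        blocks = random_block_set(rng, 40)
        v = empirical_variogram(blocks, d_max_vox=16)
        assert v.distances.max() <= 16
        assert v.full_distances.max() > 16
        assert int(v.full_pair_counts.sum()) == pair_count(40)

    def test_scaling_and_shift_invariance(self, rng):
        blocks = random_block_set(rng, 25)
        base = empirical_variogram(blocks, d_max_vox=100)
        shifted = block_set(blocks.centroids, blocks.mean_hu + 123.0)
        assert np.allclose(
            empirical_variogram(shifted, 100).gamma, base.gamma, rtol=1e-9
        )
        scaled = block_set(blocks.centroids, blocks.mean_hu * 3.0)
        assert np.allclose(
            empirical_variogram(scaled, 100).gamma, 9.0 * base.gamma, rtol=1e-9
        )

    def test_insufficient_blocks(self):
        blocks = block_set([[3.5, 3.5, 3.5]], [0.0])
        with pytest.raises(InsufficientDataError):
            empirical_variogram(blocks, 56)

    def test_sill_approaches_field_variance_at_large_distance(self):
        # unit blocks tiling a full 128-cube of a correlated field: at
        # distances far beyond the correlation length gamma must flatten at
        # the block-mean variance, itself close to sigma^2
        sigma, ell = 60.0, 12.0
        f = gaussian_random_field(128, sigma, ell, seed=9)
        means = f.reshape(16, 8, 16, 8, 16, 8).mean(axis=(1, 3, 5))
        grid = (np.indices((16, 16, 16)).reshape(3, -1).T) * 8.0 + 3.5
        blocks = block_set(grid, means.ravel())
        assert len(blocks) == 4096
        v = empirical_variogram(blocks, d_max_vox=64)
        far = v.gamma[v.distances >= 48]
        assert np.all(np.abs(far - sigma**2) / sigma**2 < 0.10)


class TestAverageAndCommonGrid:
    def test_single_input_identity(self, rng):
        v = empirical_variogram(random_block_set(rng, 20), 100)
        out = average_variograms([v])
        assert np.array_equal(out.gamma, v.gamma)

    def test_two_inputs_mean(self, rng):
        blocks = random_block_set(rng, 20)
        v1 = empirical_variogram(blocks, 100)
        other = block_set(blocks.centroids, blocks.mean_hu[::-1])
        v2 = empirical_variogram(other, 100)
        out = average_variograms([v1, v2])
        assert np.allclose(out.gamma, (v1.gamma + v2.gamma) / 2)
        assert np.array_equal(out.pair_counts, v1.pair_counts + v2.pair_counts)

    def test_three_inputs_match_hand_mean(self, rng):
        blocks = random_block_set(rng, 15)
        vs = []
        for k in range(3):
            vals = block_set(blocks.centroids, blocks.mean_hu + 10.0 * k * blocks.mean_hu)
            vs.append(empirical_variogram(vals, 100))
        out = average_variograms(vs)
        hand = np.mean([v.gamma for v in vs], axis=0)
        assert np.allclose(out.gamma, hand)

    def test_mismatched_grids_raise_and_common_grid_fixes(self, rng):
        a = empirical_variogram(random_block_set(rng, 20), 100)
        b = empirical_variogram(random_block_set(rng, 12), 100)
        if not np.array_equal(a.distances, b.distances):
            with pytest.raises(AlignmentError):
                average_variograms([a, b])
        ra, rb = common_grid([a, b])
        assert np.array_equal(ra.distances, rb.distances)
        average_variograms([ra, rb])  # must not raise


class TestFitPowerLaw:
    def test_exact_model_recovery(self, rng):
        v = empirical_variogram(random_block_set(rng, 30), 1000)
        v.gamma = 2.0 * v.distances**0.5
        fit = fit_power_law(v)
        assert fit.coefficient == pytest.approx(2.0, rel=1e-9)
        assert fit.exponent == pytest.approx(0.5, abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_constant_gamma_gives_zero_exponent(self, rng):
        v = empirical_variogram(random_block_set(rng, 30), 1000)
        v.gamma = np.full_like(v.gamma, 7.5)
        fit = fit_power_law(v)
        assert fit.exponent == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficient == pytest.approx(7.5, rel=1e-9)

    def test_matches_independent_regression_oracle(self, rng):
        v = empirical_variogram(random_block_set(rng, 40), 1000)
        v.gamma = np.abs(v.gamma) + 1.0
        fit = fit_power_law(v)
        # normal equations, assembled by hand
        x, y = np.log(v.distances), np.log(v.gamma)
        xbar, ybar = x.mean(), y.mean()
        slope = ((x - xbar) @ (y - ybar)) / ((x - xbar) @ (x - xbar))
        intercept = ybar - slope * xbar
        assert fit.exponent == pytest.approx(slope, rel=1e-9)
        assert fit.coefficient == pytest.approx(np.exp(intercept), rel=1e-9)

    def test_zero_gamma_dropped_with_warning(self, rng):
        v = empirical_variogram(random_block_set(rng, 20), 1000)
        v.gamma = 3.0 * v.distances**1.2
        v.gamma[0] = 0.0
        with pytest.warns(UserWarning):
            fit = fit_power_law(v)
        assert fit.exponent == pytest.approx(1.2, abs=1e-9)

    def test_too_few_points(self):
        blocks = block_set([[3.5, 3.5, 3.5], [11.5, 3.5, 3.5]], [1.0, 2.0])
        v = empirical_variogram(blocks, 56)
        with pytest.raises(InsufficientDataError):
            fit_power_law(v)
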
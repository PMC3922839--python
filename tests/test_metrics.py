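import itertools

import numpy as np
import pytest
from scipy import stats

from octovario import (
    AlignmentError,
    EmptyMaskError,
    GaussianFit,
    ParameterError,
    calibrate_threshold,
    coefficient_of_variation,
    emphysema_index,
    emphysema_threshold,
    fit_lung_peak_gaussian,
    heterogeneity_score,
    kruskal_wallis_test,
    mann_whitney_test,
)
from conftest import make_volume


def volume_from_values(values):
    """Pack a 1D sample into a cube; padding voxels carry the background
    sentinel and are therefore excluded from every metric."""
    n = int(np.ceil(len(values) ** (1 / 3)))
    data = np.full(n**3, 10_000.0, dtype=np.float32)
    data[: len(values)] = values
    return make_volume(data.reshape(n, n, n), background=10_000.0)


def gaussian_fit(mean, sigma):
    return GaussianFit(mean_hu=mean, sigma_hu=sigma, bin_width_hu=10.0, fit_range=(mean - 150, mean + 150))


class TestFitLungPeakGaussian:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(0)
        vol = volume_from_values(rng.normal(-550, 60, 100_000))
        fit = fit_lung_peak_gaussian(vol)
        assert fit.mean_hu == pytest.approx(-550, abs=0.02 * 550)
        assert fit.sigma_hu == pytest.approx(60, rel=0.02)

    def test_windowed_fit_tracks_dominant_mode_not_global_mean(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(-530, 50, 80_000), rng.normal(-800, 50, 20_000)]
        )
        vol = volume_from_values(values)
        fit = fit_lung_peak_gaussian(vol)
        global_mean = values.mean()  # moment oracle, pulled to ~ -584
        assert abs(fit.mean_hu - (-530)) < 15
        assert abs(fit.mean_hu - global_mean) > 30

    def test_empty_mask_errors(self):
        vol = make_volume(np.zeros((8, 8, 8)))  # everything == background
        with pytest.raises(EmptyMaskError):
            fit_lung_peak_gaussian(vol)


class TestThresholdCalibration:
    def test_study_sweep_from_sixty(self):
        fits = [gaussian_fit(-599, s) for s in (59, 60, 61)]
        cal = calibrate_threshold(fits)
        assert cal.sigma_bar_hu == 60
        assert cal.sweep_hu == (20, 40, 60, 80, 120)

    def test_single_sigma_sweep(self):
        cal = calibrate_threshold([gaussian_fit(-550, 30)])
        assert cal.sweep_hu == (10, 20, 30, 40, 60)

    def test_equal_sigmas(self):
        cal = calibrate_threshold([gaussian_fit(-550, 45)] * 4)
        assert cal.sigma_bar_hu == 45

    def test_empty_input(self):
        with pytest.raises(ParameterError):
            calibrate_threshold([])


class TestEmphysemaThresholdAndIndex:
    def test_threshold_from_study_fit_values(self):
        # Gaussian-fit control peak at -599 with sigma 59 puts the cutoff at
        # -717 HU, two sigmas below the control mean
        assert emphysema_threshold([gaussian_fit(-599, 59)]) == pytest.approx(-717)

    def test_threshold_simple_arithmetic(self):
        assert emphysema_threshold([gaussian_fit(0, 10)]) == pytest.approx(-20)
        fits = [gaussian_fit(-600, 50), gaussian_fit(-500, 60)]
        assert emphysema_threshold(fits) == pytest.approx(-660)

    def test_index_counts_fraction_below(self):
        vol = volume_from_values(np.array([-800.0] * 3 + [-500.0] * 7))
        assert emphysema_index(vol, -700) == pytest.approx(30.0)
        assert emphysema_index(vol, -900) == 0.0

    def test_index_matches_normal_tail(self):
        rng = np.random.default_rng(2)
        vol = volume_from_values(rng.normal(-550, 60, 200_000))
        got = emphysema_index(vol, -717)
        expected = 100 * stats.norm.cdf((-717 + 550) / 60)  # ~0.27%
        assert got == pytest.approx(expected, abs=0.08)

    def test_index_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vol = volume_from_values(rng.normal(-550, 60, 5_000))
        values = [emphysema_index(vol, t) for t in (-750, -700, -650, -600, -550)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestCoV:
    def test_reference_values(self):
        assert coefficient_of_variation(gaussian_fit(-600, 60)) == pytest.approx(0.10)
        # the healthy-control peak of the study this emulates: -544 +/- 58
        assert coefficient_of_variation(gaussian_fit(-544, 58)) == pytest.approx(
            58 / 544, rel=1e-9
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ParameterError):
            coefficient_of_variation(gaussian_fit(0.0, 10))


def simple_variogram(gamma):
    gamma = np.asarray(gamma, dtype=float)
    from octovario import Variogram

    return Variogram(
        distances=8.0 * np.arange(1, len(gamma) + 1),
        gamma=gamma,
        pair_counts=np.full(len(gamma), 10),
        d_max_vox=8.0 * len(gamma),
        n_blocks=100,
    )


class TestHeterogeneityScore:
    def test_zero_for_identical_curves(self, rng):
        g = rng.random(6) * 1000
        assert heterogeneity_score(simple_variogram(g), simple_variogram(g)) == 0.0

    def test_constant_offset_gives_offset(self, rng):
        g = rng.random(6) * 1000
        assert heterogeneity_score(
            simple_variogram(g + 37.0), simple_variogram(g)
        ) == pytest.approx(37.0)

    def test_matches_hand_computed_mean_absolute_difference(self, rng):
        a, b = rng.random(8) * 1000, rng.random(8) * 1000
        got = heterogeneity_score(simple_variogram(a), simple_variogram(b))
        assert got == pytest.approx(np.mean(np.abs(a - b)))

    def test_signed_mode(self):
        a = np.array([10.0, 30.0])
        b = np.array([20.0, 20.0])
        assert heterogeneity_score(
            simple_variogram(a), simple_variogram(b), signed=True
        ) == pytest.approx(0.0)

    def test_grid_mismatch(self, rng):
        with pytest.raises(AlignmentError):
            heterogeneity_score(simple_variogram(rng.random(4)), simple_variogram(rng.random(5)))


def kw_h_statistic(groups):
    """Rank-based H with tie correction, assembled from the textbook formula."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        res = kruskal_wallis_test([[5.0, 5.0, 5.0]] * 3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_group_statistic_matches_textbook_formula_and_permutations(self):
        groups = [[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]]
        res = kruskal_wallis_test(groups)
        h_ref = kw_h_statistic([np.array(g) for g in groups])
        assert res.statistic == pytest.approx(h_ref)
        # complete separation: no permutation of group labels exceeds this H
        pooled = np.array(groups[0] + groups[1])
        h_all = [
            kw_h_statistic([pooled[list(c)], np.delete(pooled, list(c))])
            for c in itertools.combinations(range(6), 3)
        ]
        assert res.statistic == pytest.approx(max(h_all))
        assert res.p_value == pytest.approx(stats.chi2.sf(h_ref, df=1))

    def test_validation(self):
        with pytest.raises(ParameterError):
            kruskal_wallis_test([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            kruskal_wallis_test([[1.0, 2.0], []])


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        res = mann_whitney_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9
        assert not res.significant

    def test_complete_separation_matches_exact_enumeration(self):
        a, b = list(range(1, 6)), list(range(11, 16))
        res = mann_whitney_test([float(x) for x in a], [float(x) for x in b])
        assert res.statistic in (0.0, 25.0)
        # exact two-sided p by enumerating all C(10, 5) labelings
        pooled = np.array(a + b, dtype=float)
        ranks = stats.rankdata(pooled)
        observed_u = min(res.statistic, 25.0 - res.statistic)
        count = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            r = ranks[list(combo)].sum()
            u = r - 5 * 6 / 2
            u = min(u, 25 - u)
            total += 1
            if u <= observed_u:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_validation(self):
        with pytest.raises(ParameterError):
            mann_whitney_test([], [1.0])
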
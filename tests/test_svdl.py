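"""Statistical voxel dose learning: binning, bin estimators and prediction."""

import numpy as np
import pytest
from scipy import stats

from liverkbp import (
    CapabilityError,
    build_distance_dose_table,
    case_distances,
    estimate_bins,
    predict_dose_3d,
    predict_dvh,
    predict_v15_svdl,
    predict_voxel_doses,
)
from liverkbp.phantoms import PhantomSpec, generate_phantom
from liverkbp.svdl import (
    BinEstimatorSet,
    DistanceDoseTable,
    fit_skew_normal,
    gaussian_kernel_resample,
    silverman_bandwidth,
)


def small_phantom(seed=0, noise=0.0, falloff=10.0):
    return generate_phantom(PhantomSpec(
        case_id=f"p{seed}", shape=(34, 34, 34), spacing=(5.0, 5.0, 5.0),
        liver_semi_axes=(65.0, 60.0, 55.0), ptv_radius=18.0,
        prescription=50.0, falloff_scale=falloff, noise_sd=noise, seed=seed))


def single_bin_estimator(method, **payload):
    est = BinEstimatorSet(method=method,
                          bin_edges=np.array([0.0, 1000.0]),
                          bin_counts=np.array([100]), **payload)
    if est.fallback is None:
        est.fallback = np.array([False])
    return est


class TestDistanceDoseTable:
    def test_sample_count_conserved(self):
        case = small_phantom()
        table = build_distance_dose_table([case], 5.0)
        assert table.n_samples == int(case.oar_mask.sum())
        assert table.n_patients == 1

    def test_pooling_two_identical_cases_doubles_counts(self):
        case = small_phantom()
        t1 = build_distance_dose_table([case], 5.0)
        t2 = build_distance_dose_table([case, case], 5.0)
        for b1, b2 in zip(t1.bins, t2.bins):
            assert b2.size == 2 * b1.size

    def test_within_bin_spread_bounded_by_lipschitz_constant(self):
        # dose = f(distance) with f 0.4 Gy/mm-Lipschitz: each bin's dose
        # range can be at most |f'|_max * bin_width
        case = small_phantom()
        d = case_distances(case)
        slope = 0.4
        dose = 60.0 - slope * np.clip(d, 0.0, None)
        case.dose[case.oar_mask] = dose
        bw = 5.0
        table = build_distance_dose_table([case], bw)
        for b in table.bins:
            if b.size:
                assert b.max() - b.min() <= slope * bw + 1e-9

    def test_empty_cohort_rejected(self):
        from liverkbp import CohortError
        with pytest.raises(CohortError):
            build_distance_dose_table([], 2.5)


class TestEstimateBins:
    def test_median_of_three(self):
        table = DistanceDoseTable(bin_edges=np.array([0.0, 2.5]),
                                  bins=[np.array([10.0, 20.0, 30.0])],
                                  n_patients=1)
        est = estimate_bins(table, "median")
        assert est.scalar[0] == 20.0

    def test_mean_and_mode(self):
        samples = np.array([10.0, 10.1, 10.2, 30.0, 30.1])
        table = DistanceDoseTable(bin_edges=np.array([0.0, 2.5]),
                                  bins=[samples], n_patients=1)
        assert estimate_bins(table, "mean").scalar[0] == pytest.approx(samples.mean())
        # mode: most populated 0.5 Gy histogram cell is [10, 10.5) -> 10.25
        assert estimate_bins(table, "mode").scalar[0] == pytest.approx(10.25)

    @pytest.mark.parametrize("alpha", [0.0, 2.0, 5.0])
    def test_skew_normal_parameter_recovery(self, alpha):
        # tolerance: 5% relative, measured against the scale when the true
        # parameter is zero; averaged over replicate fits because alpha-hat's
        # sampling sd at n=10,000 is comparable to the tolerance
        xi, omega = 20.0, 5.0
        fits = [fit_skew_normal(stats.skewnorm.rvs(
            alpha, loc=xi, scale=omega, size=10_000, random_state=100 + rep))
            for rep in range(5)]
        xi_h, om_h, a_h = np.mean(fits, axis=0)
        tol = lambda true: 0.05 * max(abs(true), omega)
        assert abs(xi_h - xi) <= tol(xi)
        assert abs(om_h - omega) <= tol(omega)
        assert abs(a_h - alpha) <= tol(alpha)

    def test_non_parametric_bins_have_exactly_10000_points(self):
        rng = np.random.default_rng(1)
        table = DistanceDoseTable(
            bin_edges=np.array([0.0, 2.5, 5.0]),
            bins=[rng.uniform(10, 30, 57), rng.uniform(5, 25, 430)],
            n_patients=2)
        est = estimate_bins(table, "non_parametric", rng=0)
        for r in est.resamples:
            assert r.size == 10_000

    def test_resample_preserves_moments_within_kernel_inflation(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(30.0, 4.0, 2000)
        h = silverman_bandwidth(samples)
        out = gaussian_kernel_resample(samples, 100_000, np.random.default_rng(3))
        assert out.mean() == pytest.approx(samples.mean(), abs=0.1)
        assert out.var() == pytest.approx(samples.var() + h ** 2, rel=0.05)

    @pytest.mark.parametrize("method", ["skew_normal", "non_parametric"])
    def test_sparse_bins_fall_back_to_median(self, method):
        table = DistanceDoseTable(
            bin_edges=np.array([0.0, 2.5, 5.0]),
            bins=[np.array([10.0, 20.0, 30.0]),  # 3 < 5 samples
                  np.random.default_rng(0).normal(20, 3, 500)],
            n_patients=1)
        est = estimate_bins(table, method, rng=0)
        assert est.fallback[0] and not est.fallback[1]
        assert est.scalar[0] == 20.0

    def test_estimation_is_seed_reproducible(self):
        rng = np.random.default_rng(4)
        table = DistanceDoseTable(bin_edges=np.array([0.0, 2.5]),
                                  bins=[rng.uniform(0, 50, 200)], n_patients=1)
        a = estimate_bins(table, "non_parametric", rng=7)
        b = estimate_bins(table, "non_parametric", rng=7)
        np.testing.assert_array_equal(a.resamples[0], b.resamples[0])


class TestPrediction:
    def test_scalar_lookup_and_clamping(self):
        est = BinEstimatorSet(method="median",
                              bin_edges=np.array([0.0, 2.5, 5.0, 7.5]),
                              bin_counts=np.array([4, 4, 4]),
                              scalar=np.array([40.0, 30.0, 20.0]))
        doses = predict_voxel_doses(est, np.array([6.0, -10.0, 99.0]))
        np.testing.assert_array_equal(doses, [20.0, 40.0, 20.0])

    def test_queries_in_empty_bins_snap_to_nearest_populated(self):
        est = BinEstimatorSet(method="median",
                              bin_edges=np.array([0.0, 2.5, 5.0, 7.5]),
                              bin_counts=np.array([4, 0, 4]),
                              scalar=np.array([40.0, np.nan, 20.0]))
        doses = predict_voxel_doses(est, np.array([3.0, 4.9]))
        assert not np.isnan(doses).any()

    def test_point_mass_dvh(self):
        est = single_bin_estimator("median", scalar=np.array([50.0]))
        dvh = predict_dvh(est, np.zeros(10), dose_step=1.0)
        assert dvh.at(0.0) == 1.0
        assert dvh.at(49.0) == 1.0
        assert dvh.at(51.0) == 0.0

    def test_two_voxel_step_dvh(self):
        est = BinEstimatorSet(method="median",
                              bin_edges=np.array([0.0, 2.5, 5.0]),
                              bin_counts=np.array([3, 3]),
                              scalar=np.array([30.0, 10.0]))
        dvh = predict_dvh(est, np.array([1.0, 4.0]), dose_step=1.0)
        assert dvh.at(5.0) == 1.0
        assert dvh.at(20.0) == 0.5
        assert dvh.at(31.0) == 0.0

    def test_symmetric_skew_normal_dvh_is_half_at_location(self):
        est = single_bin_estimator(
            "skew_normal", skew_params=np.array([[20.0, 5.0, 0.0]]),
            scalar=np.array([np.nan]))
        dvh = predict_dvh(est, np.zeros(50), dose_step=0.1)
        assert dvh.at(20.0) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("scalar,expected", [(10.0, 100.0), (20.0, 0.0)])
    def test_v15_extremes(self, scalar, expected):
        est = single_bin_estimator("median", scalar=np.array([scalar]))
        assert predict_v15_svdl(est, np.zeros(8)) == expected

    def test_v15_of_normal_centered_on_threshold_is_half(self):
        est = single_bin_estimator(
            "skew_normal", skew_params=np.array([[15.0, 3.0, 0.0]]),
            scalar=np.array([np.nan]))
        assert predict_v15_svdl(est, np.zeros(8)) == pytest.approx(50.0, abs=1e-6)

    def test_scalar_v15_consistent_with_voxel_doses(self):
        case = small_phantom(noise=0.02, seed=5)
        table = build_distance_dose_table([case], 5.0)
        est = estimate_bins(table, "median")
        d = case_distances(case)
        v15 = predict_v15_svdl(est, d)
        doses = predict_voxel_doses(est, d)
        assert v15 == pytest.approx(100.0 * np.mean(doses < 15.0))

    def test_dvh_monotone_nonincreasing_for_all_methods(self):
        train = [small_phantom(seed=s, noise=0.05) for s in (1, 2)]
        table = build_distance_dose_table(train, 5.0)
        d = case_distances(small_phantom(seed=3))
        for method in ("median", "mean", "mode", "skew_normal", "non_parametric"):
            est = estimate_bins(table, method, rng=0)
            dvh = predict_dvh(est, d)
            assert dvh.volume_fraction[0] == 1.0
            assert (np.diff(dvh.volume_fraction) <= 1e-12).all()
            assert dvh.volume_fraction[-1] == pytest.approx(0.0, abs=1e-6)


class TestDose3D:
    def test_fitting_methods_cannot_predict_3d(self):
        est = single_bin_estimator(
            "skew_normal", skew_params=np.array([[20.0, 5.0, 0.0]]),
            scalar=np.array([np.nan]))
        with pytest.raises(CapabilityError):
            predict_dose_3d(est, small_phantom())

    def test_single_voxel_oar(self):
        case = small_phantom()
        table = build_distance_dose_table([case], 5.0)
        est = estimate_bins(table, "median")
        one = case.oar_mask & False
        idx = np.argwhere(case.oar_mask)[0]
        one[tuple(idx)] = True
        query = type(case)(case_id="one", oar_mask=one,
                           target_mask=case.target_mask, dose=case.dose,
                           spacing=case.spacing, prescription=50.0)
        grid = predict_dose_3d(est, query)
        assert np.isfinite(grid[one]).all()
        assert np.isnan(grid[~one]).all()

    def test_distance_deterministic_case_recovered_within_bin_tolerance(self):
        # identical fall-off everywhere: predicted grid must equal actual up
        # to the within-bin dose variation
        train = [small_phantom(seed=s) for s in (1, 2, 3)]
        query = small_phantom(seed=9)
        table = build_distance_dose_table(train, 5.0)
        est = estimate_bins(table, "median")
        grid = predict_dose_3d(est, query)
        err = np.abs(grid[query.oar_mask] - query.dose[query.oar_mask])
        # steepest gradient of the shared fall-off * bin width bounds the error
        d = np.linspace(-5, 100, 2000)
        from liverkbp.phantoms import dose_falloff
        g = 50.0 * dose_falloff(d / 10.0)
        max_grad = np.abs(np.diff(g) / np.diff(d)).max()
        assert err.max() <= max_grad * 5.0 + 1e-6
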
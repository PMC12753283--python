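"""Spatial kernels, bandwidth selection, locally weighted fitting."""

import numpy as np
import pytest

from gwwr import (GWWR, KernelConfig, WeibullRegression, kernel_weights,
                  local_fit, optimize_bandwidth, pairwise_distances)
from gwwr.gwmodel import UnderIdentifiedError, default_candidate_grid
from gwwr.model import gradient, hessian, loglik
from gwwr.simulate import SimulationConfig, global_truth_config, simulate

from conftest import make_sample


class TestDistances:
    def test_three_four_five(self):
        D = pairwise_distances([[0, 0], [3, 4]])
        assert D[0, 1] == pytest.approx(5.0)

    def test_zero_diagonal_symmetric_triangle(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (10, 2))
        D = pairwise_distances(pts)
        np.testing.assert_array_equal(np.diag(D), 0.0)
        np.testing.assert_allclose(D, D.T)
        brute = np.array([[np.hypot(*(a - b)) for b in pts] for a in pts])
        np.testing.assert_allclose(D, brute, rtol=1e-12)
        for i, j, k in [(0, 3, 7), (1, 5, 9), (2, 4, 6)]:
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


class TestKernels:
    def test_weight_one_at_zero_distance(self):
        for kind in ("gaussian", "bisquare"):
            assert kernel_weights([0.0], 2.0, kind)[0] == 1.0

    def test_gaussian_at_bandwidth(self):
        assert kernel_weights([2.0], 2.0, "gaussian")[0] == \
            pytest.approx(np.exp(-0.5))

    def test_bisquare_support_and_value(self):
        assert kernel_weights([3.0], 2.0, "bisquare")[0] == 0.0
        a = 2.0
        assert kernel_weights([a / np.sqrt(2)], a, "bisquare")[0] == \
            pytest.approx(0.25)

    def test_infinite_bandwidth_unit_weights(self):
        d = np.linspace(0, 100, 7)
        for kind in ("gaussian", "bisquare"):
            np.testing.assert_array_equal(
                kernel_weights(d, np.inf, kind), 1.0)

    def test_monotone_decay(self):
        d = np.linspace(0, 5, 50)
        for kind in ("gaussian", "bisquare"):
            w = kernel_weights(d, 2.0, kind)
            assert np.all(np.diff(w) <= 1e-15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_weights([-1.0], 1.0)


class TestWeightedLikelihood:
    def test_unit_weights_reduce_to_global(self, small_sample):
        phi = np.array([1.5, -2.0] + [0.1] * small_sample.p)
        w = np.ones(small_sample.n)
        assert loglik(phi, small_sample, w) == \
            pytest.approx(loglik(phi, small_sample), abs=1e-12)
        np.testing.assert_allclose(gradient(phi, small_sample, w),
                                   gradient(phi, small_sample), rtol=1e-14)

    def test_weight_two_equals_duplicated_row(self):
        y = [1.0, 2.5, 3.0, 1.7]
        d = [1, 1, 0, 1]
        X = [[0.3], [-0.2], [0.5], [0.1]]
        s = make_sample(y, d, X, threshold=3.0)
        s_dup = make_sample(y + [y[0]], d + [d[0]], X + [X[0]], threshold=3.0)
        phi = np.array([1.3, -0.4, 0.2])
        w = np.array([2.0, 1.0, 1.0, 1.0])
        assert loglik(phi, s, w) == pytest.approx(loglik(phi, s_dup),
                                                  rel=1e-12)
        np.testing.assert_allclose(gradient(phi, s, w),
                                   gradient(phi, s_dup), rtol=1e-12)
        np.testing.assert_allclose(hessian(phi, s, w),
                                   hessian(phi, s_dup), rtol=1e-12)

    def test_weighted_derivatives_match_finite_differences(self, small_sample):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.1, 1.0, small_sample.n)
        phi = np.array([1.2, -1.5] + [0.05] * small_sample.p)
        h = 1e-6
        eye = np.eye(phi.size)
        fd_g = np.array([(loglik(phi + h * e, small_sample, w)
                          - loglik(phi - h * e, small_sample, w)) / (2 * h)
                         for e in eye])
        np.testing.assert_allclose(gradient(phi, small_sample, w), fd_g,
                                   rtol=1e-4, atol=1e-6)
        fd_H = np.column_stack([
            (gradient(phi + 1e-5 * e, small_sample, w)
             - gradient(phi - 1e-5 * e, small_sample, w)) / 2e-5
            for e in eye])
        np.testing.assert_allclose(hessian(phi, small_sample, w), fd_H,
                                   rtol=1e-3, atol=1e-4)

    def test_bisquare_compact_support_zero_contribution(self, small_sample):
        D = pairwise_distances(small_sample.coords)
        a = np.median(D[0][D[0] > 0])
        w = kernel_weights(D[0], a, "bisquare")
        far = D[0] > a
        assert np.any(far) and np.all(w[far] == 0.0)
        # removing far rows changes nothing
        phi = np.array([1.5, -2.0] + [0.0] * small_sample.p)
        keep = ~far
        sub = make_sample(small_sample.censored_response[keep],
                          small_sample.delta[keep],
                          small_sample.covariates[keep],
                          threshold=small_sample.threshold)
        assert loglik(phi, small_sample, w) == \
            pytest.approx(loglik(phi, sub, w[keep]), rel=1e-12)


class TestLocalFit:
    def test_infinite_bandwidth_matches_global(self, fixture27):
        res = WeibullRegression(fixture27).fit()
        lf = local_fit(fixture27, 0, np.inf, KernelConfig())
        np.testing.assert_allclose(lf.params.packed, res.params.packed,
                                   atol=1e-8)

    def test_local_beats_global_under_same_weights(self, fixture27):
        res = WeibullRegression(fixture27).fit()
        D = pairwise_distances(fixture27.coords)
        a = np.median(D[D > 0])
        lf = local_fit(fixture27, 3, a, KernelConfig(),
                       init=res.params.packed)
        assert lf.loglik >= loglik(res.params.packed, fixture27, lf.weights)

    def test_under_identified_bandwidth_flagged(self, fixture27):
        with pytest.raises(UnderIdentifiedError):
            local_fit(fixture27, 0, 1e-6, KernelConfig(kind="bisquare"))

    def test_spatially_constant_truth_recovered_locally(self):
        cfg = global_truth_config(n_sites=150, seed=5, shape=5.0,
                                  coef=(-10.0, 0.8))
        sample, truth = simulate(cfg)
        D = pairwise_distances(sample.coords)
        a = np.median(D)
        full = np.array([5.0, -10.0, 0.8])
        for i in (0, 50, 100):
            lf = local_fit(sample, i, a, KernelConfig(), distances=D)
            assert np.all(np.abs(lf.params.packed - full) < 3 * lf.bse)


class TestBandwidthSearch:
    def test_single_candidate_returned(self, fixture27):
        cfg = KernelConfig(include_infinite=False)
        a, trace = optimize_bandwidth(fixture27, 0, cfg, grid=[2.5])
        assert a == 2.5 and len(trace) == 1

    def test_argmin_over_grid(self, fixture27):
        cfg = KernelConfig()
        a, trace = optimize_bandwidth(fixture27, 4, cfg)
        bics = {bw: b for bw, b in trace if np.isfinite(b)}
        assert min(bics.values()) == pytest.approx(bics[a])
        # re-evaluate the winner independently
        lf = local_fit(fixture27, 4, a, cfg)
        assert lf.bic == pytest.approx(bics[a], rel=1e-10)

    def test_no_spurious_heterogeneity_at_large_bandwidth(self):
        # under a spatially constant truth, large-bandwidth local fits sit
        # on top of the global fit site by site -- no heterogeneity is
        # invented where none exists
        cfg_data = global_truth_config(n_sites=60, seed=0, shape=5.0,
                                       coef=(-10.0, 0.8))
        sample, _ = simulate(cfg_data, seed=1000)
        res = WeibullRegression(sample).fit()
        D = pairwise_distances(sample.coords)
        kernel = KernelConfig()
        for i in (0, 20, 40):
            lf = local_fit(sample, i, 1e6 * D.max(), kernel, distances=D)
            np.testing.assert_allclose(lf.params.packed, res.params.packed,
                                       atol=1e-6)

    def test_default_grid_spans_nn_to_double_max_distance(self, fixture27):
        kernel = KernelConfig(n_candidates=12)
        D = pairwise_distances(fixture27.coords)
        grid = default_candidate_grid(fixture27, 0, kernel, distances=D)
        assert grid.size == 12
        assert grid[0] == pytest.approx(
            np.sort(D[0])[fixture27.p + 2], rel=1e-12)
        assert grid[-1] == pytest.approx(2.0 * D.max(), rel=1e-12)

    def test_effective_n_penalty_variant(self, fixture27):
        D = pairwise_distances(fixture27.coords)
        a = 0.75 * D.max()
        lf_full = local_fit(fixture27, 0, a, KernelConfig(), distances=D)
        lf_eff = local_fit(fixture27, 0, a,
                           KernelConfig(bic_effective_n=True), distances=D)
        K = fixture27.p + 2
        expected = lf_full.bic - K * np.log(fixture27.n) \
            + K * np.log(lf_eff.weights.sum())
        assert lf_eff.bic == pytest.approx(expected, rel=1e-12)

    def test_all_under_identified_raises(self, fixture27):
        cfg = KernelConfig(kind="bisquare", include_infinite=False)
        with pytest.raises(UnderIdentifiedError):
            optimize_bandwidth(fixture27, 0, cfg, grid=[1e-8, 1e-7])


class TestGWWRFit:
    def test_unit_weight_config_reproduces_global(self, fixture27):
        gw = GWWR(fixture27, KernelConfig(bandwidth_mode="fixed",
                                          fixed_bandwidth=np.inf)).fit()
        gphi = gw.global_results.params.packed
        for lf in gw.local_fits:
            np.testing.assert_allclose(lf.params.packed, gphi, atol=1e-8)

    def test_deterministic_rerun(self, fixture27):
        cfg = KernelConfig(n_candidates=10)
        r1 = GWWR(fixture27, cfg).fit()
        r2 = GWWR(fixture27, cfg).fit()
        np.testing.assert_array_equal(r1.coef_matrix(), r2.coef_matrix())
        np.testing.assert_array_equal(r1.bandwidths, r2.bandwidths)

    def test_linear_coefficient_surface_recovered(self):
        cfg = SimulationConfig(
            n_sites=80,
            coefficient_surfaces=[("linear", -11.0, 2.0, 0.0),
                                  ("linear", -0.8, 1.6, 0.0)],
            shape_surface=("constant", 5.0),
            covariate_distributions=[("normal", 0.0, 1.0)],
            censor_threshold=8.0, seed=13)
        sample, truth = simulate(cfg)
        gw = GWWR(sample, KernelConfig(n_candidates=15)).fit()
        est_b1 = gw.coef_matrix()[:, 2]
        ok = np.isfinite(est_b1)
        r = np.corrcoef(est_b1[ok], truth.coef[ok, 1])[0, 1]
        assert r > 0.7

    def test_bandwidth_to_infinity_limit(self, fixture27):
        D = pairwise_distances(fixture27.coords)
        huge = 1e6 * D.max()
        res = WeibullRegression(fixture27).fit()
        lf = local_fit(fixture27, 7, huge, KernelConfig())
        np.testing.assert_allclose(lf.params.packed, res.params.packed,
                                   atol=1e-6)

    def test_local_params_table_shape(self, fixture27):
        gw = GWWR(fixture27, KernelConfig(n_candidates=8)).fit()
        tab = gw.local_params_table()
        assert len(tab) == 27
        assert "bandwidth" in tab.columns and "b[Intercept]" in tab.columns
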
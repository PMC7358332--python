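import numpy as np
import pytest
from scipy.stats import spearmanr

from slowgc import (
    RegionalScan,
    VARModel,
    conditional_gc_pair,
    fit_var,
    gc_matrices,
    lagged_covariance,
    one_stage_gc,
    partial_correlation,
    population_gc_matrices,
    select_order_aic,
    simulate_var,
    stationary_cov_var,
    var_autocovariances,
)
from conftest import naive_conditional_gc


class TestFitVar:
    def test_recovers_ar_coefficient(self):
        model = VARModel(order=1, coeffs=[np.array([[0.9]])], resid_cov=np.eye(1), n_obs=0)
        scan = RegionalScan(data=simulate_var(model, 5000, seed=0), tr=1.0)
        fit = fit_var(scan, 1)
        assert abs(fit.coeffs[0][0, 0] - 0.9) < 0.05

    def test_white_noise_gives_null_fit(self, white_scan):
        fit = fit_var(white_scan, 1)
        assert np.abs(fit.coeffs[0]).max() < 0.15
        np.testing.assert_allclose(fit.resid_cov, np.eye(3), atol=0.2)

    def test_segmented_fit_equals_pair_pooled_oracle(self, rng):
        """Two segments cut from one series equal a fit with the junction-
        spanning lag pairs manually removed."""
        model = VARModel(
            order=1, coeffs=[np.array([[0.6, 0.2], [0.0, 0.5]])],
            resid_cov=np.eye(2), n_obs=0,
        )
        data = simulate_var(model, 300, seed=5)
        scan = RegionalScan(data=data, tr=1.0, segments=[(0, 120), (120, 300)])
        fit = fit_var(scan, 1)
        xs, ys = [], []
        for a, b in scan.segments:
            seg = data[a:b] - data[a:b].mean(axis=0)
            xs.append(seg[:-1])
            ys.append(seg[1:])
        x = np.vstack(xs)
        y = np.vstack(ys)
        beta = np.linalg.lstsq(x, y, rcond=None)[0].T
        np.testing.assert_allclose(fit.coeffs[0], beta, atol=1e-10)

    def test_rank_deficient_names_columns(self, rng):
        data = rng.standard_normal((100, 2))
        data = np.column_stack([data, data[:, 0]])  # duplicated region
        with pytest.raises(np.linalg.LinAlgError, match="dependent columns"):
            fit_var(RegionalScan(data=data, tr=1.0), 1)


class TestOrderSelection:
    def test_var1_data_selects_order_one(self, var1_scan):
        assert select_order_aic(var1_scan, 5) == 1

    def test_var2_data_selects_order_two(self):
        a1 = np.array([[0.2, 0.0], [0.0, 0.2]])
        a2 = np.array([[0.5, 0.0], [0.3, 0.4]])
        model = VARModel(order=2, coeffs=[a1, a2], resid_cov=np.eye(2), n_obs=0)
        scan = RegionalScan(data=simulate_var(model, 3000, seed=2), tr=1.0)
        assert select_order_aic(scan, 5) == 2

    def test_white_noise_selects_smallest(self, white_scan):
        assert select_order_aic(white_scan, 4) == 1


class TestConditionalGC:
    def test_independent_series_near_zero(self, white_scan):
        t = white_scan.n_timepoints
        fij, fji, finst, ffull = conditional_gc_pair(white_scan, 0, 1, 1)
        bound = 2.0 * 1 / t * 3  # generous small-sample bias bound
        for term in (fij, fji, finst):
            assert abs(term) < 3 * bound
        assert abs(ffull) < 4 * bound

    def test_population_directed_structure(self, var1_model):
        gc = population_gc_matrices(var1_model)
        assert gc.dgc[1, 0] > 0.05  # region 0 drives region 1
        assert gc.dgc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert gc.igc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_additivity_identity(self, var1_scan):
        fij, fji, finst, ffull = conditional_gc_pair(var1_scan, 0, 1, 1)
        assert ffull == pytest.approx(fij + fji + finst, abs=1e-12)

    def test_population_nonnegative(self, rng):
        a = rng.uniform(-0.3, 0.3, (4, 4))
        a *= 0.8 / np.max(np.abs(np.linalg.eigvals(a)))
        s = rng.standard_normal((4, 4))
        model = VARModel(order=1, coeffs=[a], resid_cov=s @ s.T / 4 + np.eye(4), n_obs=0)
        gc = population_gc_matrices(model)
        assert gc.dgc.min() >= -1e-12
        assert gc.igc.min() >= -1e-12

    @pytest.mark.parametrize("r,t,seed", [(3, 400, 7), (4, 300, 11)])
    def test_matches_naive_two_regression_oracle(self, r, t, seed, rng):
        a = np.random.default_rng(seed).uniform(-0.4, 0.4, (r, r))
        a *= 0.7 / np.max(np.abs(np.linalg.eigvals(a)))
        model = VARModel(order=1, coeffs=[a], resid_cov=np.eye(r), n_obs=0)
        data = simulate_var(model, t, seed=seed)
        scan = RegionalScan(data=data, tr=1.0)
        for i in range(r):
            for j in range(i + 1, r):
                ours = conditional_gc_pair(scan, i, j, 1)
                oracle = naive_conditional_gc(data, i, j, 1)
                np.testing.assert_allclose(ours, oracle, atol=1e-10)


class TestGCMatrices:
    def test_feature_counts_r14(self, rng):
        from slowgc import vectorize

        scan = RegionalScan(data=rng.standard_normal((400, 14)), tr=0.72)
        gc = gc_matrices(scan, 1)
        assert len(vectorize(gc, "igc")) == 91
        assert len(vectorize(gc, "dgc")) == 182

    def test_permutation_equivariance(self, var1_scan, rng):
        data3 = np.column_stack([var1_scan.data, rng.standard_normal(var1_scan.n_timepoints)])
        scan = RegionalScan(data=data3, tr=1.0)
        gc = gc_matrices(scan, 1)
        perm = [2, 0, 1]
        scan_p = RegionalScan(data=data3[:, perm], tr=1.0)
        gc_p = gc_matrices(scan_p, 1)
        p = np.eye(3)[perm]
        np.testing.assert_allclose(gc_p.dgc, p @ gc.dgc @ p.T, atol=1e-10)
        np.testing.assert_allclose(gc_p.igc, p @ gc.igc @ p.T, atol=1e-10)

    def test_scale_invariance(self, var1_scan):
        gc = gc_matrices(var1_scan, 1)
        scaled = RegionalScan(data=var1_scan.data * np.array([10.0, 1.0]), tr=1.0)
        gc_s = gc_matrices(scaled, 1)
        np.testing.assert_allclose(gc_s.dgc, gc.dgc, atol=1e-8)
        np.testing.assert_allclose(gc_s.igc, gc.igc, atol=1e-8)

    def test_edge_list_round_trip(self, var1_scan):
        gc = gc_matrices(var1_scan, 1)
        edges = gc.to_edge_list()
        assert len(edges[edges.measure == "dgc"]) == 2
        row = edges[(edges.measure == "dgc") & (edges.source == "0")].iloc[0]
        assert row.value == pytest.approx(gc.dgc[1, 0])

    def test_dgc_orientation_source_column(self, var1_model):
        """Region 0 drives region 1, so the entry (row=1, col=0) is positive."""
        gc = population_gc_matrices(var1_model)
        assert gc.dgc[1, 0] > 0 and gc.dgc[0, 1] == pytest.approx(0, abs=1e-12)


class TestOneStage:
    def test_strong_rank_correlation_with_two_stage(self):
        a = np.array([[0.5, 0.1, 0.0], [0.4, 0.4, 0.0], [0.0, 0.3, 0.5]])
        model = VARModel(order=1, coeffs=[a], resid_cov=np.eye(3), n_obs=0)
        scan = RegionalScan(data=simulate_var(model, 5000, seed=4), tr=1.0)
        two = gc_matrices(scan, 1, with_pc=False)
        one = one_stage_gc(scan, 1, with_pc=False)
        mask = ~np.eye(3, dtype=bool)
        rho = spearmanr(one.dgc[mask], two.dgc[mask]).statistic
        assert rho > 0.9

    def test_population_identical_to_two_stage(self, var1_model):
        """Both estimators are exact given the true model: feed the analytic
        reduced solution with the model's own autocovariances."""
        pop = population_gc_matrices(var1_model)
        # simulate a long series so the fitted full model approaches truth
        scan = RegionalScan(data=simulate_var(var1_model, 60000, seed=9), tr=1.0)
        one = one_stage_gc(scan, 1, with_pc=False)
        np.testing.assert_allclose(one.dgc, pop.dgc, atol=0.02)

    def test_zero_coupling_near_zero(self, white_scan):
        one = one_stage_gc(white_scan, 1, with_pc=False)
        assert np.abs(one.dgc).max() < 0.05


class TestZeroLagMeasures:
    def test_pc_removes_common_driver(self, rng):
        z = rng.standard_normal(4000)
        x = z + rng.standard_normal(4000)
        y = z + rng.standard_normal(4000)
        scan = RegionalScan(data=np.column_stack([x, y, z]), tr=1.0)
        pc = partial_correlation(scan)
        pearson_xy = np.corrcoef(x, y)[0, 1]
        assert pearson_xy > 0.3
        assert abs(pc[0, 1]) < 0.08
        # oracle: correlation of residuals after regressing out z
        rx = x - z * (x @ z) / (z @ z)
        ry = y - z * (y @ z) / (z @ z)
        np.testing.assert_allclose(pc[0, 1], np.corrcoef(rx, ry)[0, 1], atol=0.02)

    def test_diagonal_cov_zero_offdiag(self, rng):
        scan = RegionalScan(data=rng.standard_normal((2000, 4)) * [1, 2, 3, 4], tr=1.0)
        pc = partial_correlation(scan)
        assert np.abs(pc - np.eye(4)).max() < 0.08

    def test_two_regions_equals_pearson(self, var1_scan):
        pc = partial_correlation(var1_scan)
        pearson = np.corrcoef(var1_scan.data.T)[0, 1]
        assert pc[0, 1] == pytest.approx(pearson, abs=1e-10)

    def test_lag0_is_sample_covariance(self, white_scan):
        c = lagged_covariance(white_scan, 0).matrix
        demeaned = white_scan.data - white_scan.data.mean(axis=0)
        np.testing.assert_allclose(c, demeaned.T @ demeaned / len(demeaned), atol=1e-12)

    def test_yule_walker_lag1_identity(self, var1_model):
        g0 = stationary_cov_var(var1_model)
        g1 = var_autocovariances(var1_model, 1)[1]
        np.testing.assert_allclose(g1, var1_model.coeffs[0] @ g0, atol=1e-10)

    def test_lagged_cov_carries_extra_noise(self, var1_model):
        """The lag-1 covariance estimate decomposes as A Sigma0_hat plus a
        noise-interaction term, so its sampling variance exceeds that of the
        instantaneous-covariance component alone."""
        s0, s1 = [], []
        for rep in range(200):
            scan = RegionalScan(data=simulate_var(var1_model, 100, seed=rep), tr=1.0)
            s0.append(lagged_covariance(scan, 0).matrix)
            s1.append(lagged_covariance(scan, 1).matrix)
        a = var1_model.coeffs[0]
        v_inst_part = np.var(
            np.einsum("ij,rjk->rik", a, np.array(s0)), axis=0
        ).mean()
        v1 = np.var(np.array(s1), axis=0).mean()
        assert v1 > v_inst_part


class TestStationaryCov:
    def test_balanced_coupling_zero_cross_covariance(self):
        """Two-node VAR(1) with antisymmetric coupling (c = -d): zero-lag
        cross-covariance vanishes regardless of the recurrent strength."""
        a_self = 0.5
        coupling = np.array([[a_self, -0.2], [0.2, a_self]])
        model = VARModel(order=1, coeffs=[coupling], resid_cov=np.eye(2), n_obs=0)
        g0 = stationary_cov_var(model)
        assert abs(g0[0, 1]) < 1e-10

    def test_no_dynamics_returns_noise_cov(self, rng):
        s = rng.standard_normal((3, 3))
        sigma = s @ s.T + np.eye(3)
        model = VARModel(order=1, coeffs=[np.zeros((3, 3))], resid_cov=sigma, n_obs=0)
        np.testing.assert_allclose(stationary_cov_var(model), sigma, atol=1e-10)

    def test_defining_equation(self, rng):
        a = rng.uniform(-0.3, 0.3, (5, 5))
        a *= 0.9 / np.max(np.abs(np.linalg.eigvals(a)))
        model = VARModel(order=1, coeffs=[a], resid_cov=np.eye(5), n_obs=0)
        g0 = stationary_cov_var(model)
        resid = g0 - a @ g0 @ a.T - np.eye(5)
        assert np.abs(resid).max() < 1e-8

    def test_unstable_model_rejected(self):
        model = VARModel(order=1, coeffs=[np.array([[1.01]])], resid_cov=np.eye(1), n_obs=0)
        with pytest.raises(ValueError, match="unstable"):
            stationary_cov_var(model)


class TestPCiGCMixture:
    def test_lagged_structure_breaks_pc_igc_identity(self):
        """With nonzero lag coefficients and correlated residuals, PC differs
        from the innovation partial correlation; zeroing the lag coefficients
        restores equality within sampling error."""
        sigma = np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0], [0.0, 0.0, 1.0]])
        a = np.array([[0.5, 0.3, 0.0], [0.0, 0.5, 0.3], [0.3, 0.0, 0.5]])

        def innovation_pc(m):
            prec = np.linalg.inv(m.resid_cov)
            return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])

        with_lags = VARModel(order=1, coeffs=[a], resid_cov=sigma, n_obs=0)
        scan = RegionalScan(data=simulate_var(with_lags, 20000, seed=6), tr=1.0)
        pc = partial_correlation(scan)[0, 1]
        fit = fit_var(scan, 1)
        assert abs(pc - innovation_pc(fit)) > 0.05

        no_lags = VARModel(order=1, coeffs=[np.zeros((3, 3))], resid_cov=sigma, n_obs=0)
        scan0 = RegionalScan(data=simulate_var(no_lags, 20000, seed=6), tr=1.0)
        pc0 = partial_correlation(scan0)[0, 1]
        fit0 = fit_var(scan0, 1)
        assert abs(pc0 - innovation_pc(fit0)) < 0.02
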
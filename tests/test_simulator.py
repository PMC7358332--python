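import numpy as np
import pytest

from slowgc import (
    CohortSpec,
    ContinuousNetwork,
    HRFSpec,
    RegionalScan,
    build_cluster_network,
    discretize_ou,
    eigen_timescales,
    feedforward_two_node_network,
    generate_cohort,
    gc_matrices,
    hrf_kernel,
    neural_to_bold,
    node_average,
    population_gc_matrices,
    simulate_var,
    solve_lyapunov_continuous,
    stationary_cov_var,
)
from slowgc.simulator import default_condition_pair, discretized_noise_intensity


class TestDiscretization:
    def test_leak_only_node_is_scalar_exponential(self):
        net = ContinuousNetwork(W=np.zeros((2, 2)), tau=1.0)
        dv = discretize_ou(net, 1.0)
        np.testing.assert_allclose(dv.coeffs[0], np.exp(-1.0) * np.eye(2), atol=1e-12)

    def test_small_step_limit(self):
        net = ContinuousNetwork(W=np.array([[0.0, 0.0], [0.5, 0.0]]), tau=0.5)
        dv = discretize_ou(net, 1e-6)
        np.testing.assert_allclose(dv.coeffs[0], np.eye(2), atol=1e-5)
        # residual covariance shrinks with the step but the 1/delta-scaled
        # intensity stays finite
        assert np.abs(dv.resid_cov).max() < 1e-4
        scaled = discretized_noise_intensity(net, 1e-6)
        assert 0.1 < np.abs(scaled).max() < 10

    def test_stationary_covariance_preserved_at_any_step(self, rng):
        w = rng.uniform(-0.4, 0.4, (4, 4))
        w -= np.eye(4) * max(0.0, np.max(np.linalg.eigvals(w).real))
        net = ContinuousNetwork(W=w, tau=0.3)
        g0 = solve_lyapunov_continuous(net)
        for delta in (0.05, 0.75, 2.0):
            dv = discretize_ou(net, delta)
            np.testing.assert_allclose(stationary_cov_var(dv), g0, atol=1e-6)

    def test_scalar_lyapunov(self):
        # A = -1, Sigma = 2 => Gamma(0) = 1
        net = ContinuousNetwork(W=np.zeros((1, 1)), tau=1.0, Sigma=2 * np.eye(1))
        np.testing.assert_allclose(solve_lyapunov_continuous(net), [[1.0]], atol=1e-12)

    def test_lyapunov_residual_random_system(self, rng):
        w = rng.uniform(-0.5, 0.5, (5, 5)) * 0.5
        net = ContinuousNetwork(W=w, tau=0.2)
        g0 = solve_lyapunov_continuous(net)
        a = net.drift
        resid = a @ g0 + g0 @ a.T + net.Sigma
        assert np.abs(resid).max() < 1e-8

    def test_lyapunov_matches_monte_carlo(self):
        net = feedforward_two_node_network(0.5)
        g0 = solve_lyapunov_continuous(net)
        x = simulate_var(discretize_ou(net, 0.05), 200000, seed=0)
        emp = np.cov(x.T)
        assert np.abs(emp - g0).max() / np.abs(g0).max() < 0.05

    def test_unstable_network_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            ContinuousNetwork(W=2.0 * np.eye(2), tau=1.0)


class TestSimulateVar:
    def test_no_dynamics_identity_covariance(self):
        from slowgc import VARModel

        m = VARModel(order=1, coeffs=[np.zeros((3, 3))], resid_cov=np.eye(3), n_obs=0)
        x = simulate_var(m, 20000, seed=0)
        np.testing.assert_allclose(np.cov(x.T), np.eye(3), atol=0.05)

    def test_seed_reproducibility(self, var1_model):
        a = simulate_var(var1_model, 100, seed=42)
        b = simulate_var(var1_model, 100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_sample_lag1_covariance_yule_walker(self, var1_model):
        x = simulate_var(var1_model, 10000, seed=1)
        g0 = stationary_cov_var(var1_model)
        expected = var1_model.coeffs[0] @ g0
        emp = (x[1:] - x.mean(0)).T @ (x[:-1] - x.mean(0)) / (len(x) - 1)
        assert np.abs(emp - expected).max() / np.abs(expected).max() < 0.05


class TestHRF:
    def test_canonical_shape(self):
        spec = HRFSpec(kernel_dt=0.05)
        k = hrf_kernel(spec)
        t = np.arange(len(k)) * spec.kernel_dt
        peak = t[np.argmax(k)]
        assert 4.5 <= peak <= 6.5
        assert k.min() < 0  # undershoot
        assert t[np.argmin(k)] > peak
        assert k.max() > abs(k.min())
        assert k.sum() == pytest.approx(1.0)

    def test_latency_is_exact_shift(self):
        base = hrf_kernel(HRFSpec(onset_latency=0.0, kernel_dt=0.05))
        delayed = hrf_kernel(HRFSpec(onset_latency=3.0, kernel_dt=0.05))
        shift = int(round(3.0 / 0.05))
        assert len(delayed) == len(base) + shift
        np.testing.assert_allclose(delayed[shift:], base, atol=1e-12)
        np.testing.assert_allclose(delayed[:shift], 0.0)

    def test_zero_latency_identity(self):
        a = hrf_kernel(HRFSpec(onset_latency=0.0, kernel_dt=0.1))
        b = hrf_kernel(HRFSpec(onset_latency=0.0, kernel_dt=0.1))
        np.testing.assert_array_equal(a, b)


class TestNeuralToBold:
    def test_impulse_response_is_kernel(self):
        spec = HRFSpec(kernel_dt=0.05, length=20.0)
        k = hrf_kernel(spec)
        t_in = 3 * len(k)
        x = np.zeros((t_in, 1))
        x[len(k) + 5, 0] = 1.0  # impulse after the discarded transient
        scan = neural_to_bold(x, spec, sim_dt=0.05, tr_out=0.05)
        out = scan.data[:, 0]
        np.testing.assert_allclose(out[5 : 5 + len(k)], k, atol=1e-12)

    def test_constant_input_scaled_by_kernel_sum(self):
        spec = HRFSpec(kernel_dt=0.05, length=20.0)
        k = hrf_kernel(spec)
        x = np.full((3 * len(k), 2), 2.0)
        scan = neural_to_bold(x, spec, sim_dt=0.05, tr_out=0.25)
        np.testing.assert_allclose(scan.data, 2.0 * k.sum(), atol=1e-10)

    def test_onset_difference_shifts_cross_correlogram(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal(20000)) * 0.05
        series = np.column_stack([x, x])
        dt = 0.05
        specs = [HRFSpec(onset_latency=3.0, kernel_dt=dt),
                 HRFSpec(onset_latency=4.0, kernel_dt=dt)]
        scan = neural_to_bold(series, specs, sim_dt=dt, tr_out=dt)
        a, b = scan.data[:, 0], scan.data[:, 1]
        lags = np.arange(-40, 41)
        cc = [np.corrcoef(a[40 + l : len(a) - 40 + l], b[40 : len(b) - 40])[0, 1]
              for l in lags]
        # node 1 lags node 0 by exactly 1 s = 20 samples
        assert lags[int(np.argmax(cc))] == -20

    def test_mismatched_spec_count_rejected(self):
        with pytest.raises(ValueError, match="HRF specs"):
            neural_to_bold(np.zeros((100, 3)), [HRFSpec()] * 2, 0.05, 0.75)


class TestClusterNetworks:
    def test_nine_node_dimensions(self):
        net = build_cluster_network(9, neurons_per_node=100, seed=0)
        assert net.W.shape == (900, 900)
        assert len(np.unique(net.node_of_neuron)) == 9

    def test_no_inter_edges_block_diagonal(self):
        net = build_cluster_network(3, neurons_per_node=20, seed=1)
        for i in range(3):
            for j in range(3):
                block = net.W[i * 20 : (i + 1) * 20, j * 20 : (j + 1) * 20]
                assert (np.abs(block).max() > 0) == (i == j)

    def test_inter_edges_confined_to_designated_subset(self):
        net = build_cluster_network(
            2, neurons_per_node=100, inter_edges=[(0, 1, +1)], seed=2
        )
        n_inter = net.meta["n_inter"]
        off = net.W[100:200, 0:100]
        rows, cols = np.nonzero(off)
        assert rows.max() < n_inter and cols.max() < n_inter
        assert np.all(off[:n_inter, :n_inter] > 0)

    def test_cloned_clusters_identical_blocks(self):
        net = build_cluster_network(2, neurons_per_node=50, clone_clusters=True, seed=3)
        np.testing.assert_array_equal(net.W[:50, :50], net.W[50:, 50:])


class TestEigenTimescales:
    def test_isolated_leak_nodes(self):
        net = ContinuousNetwork(W=np.zeros((4, 4)), tau=0.05)
        np.testing.assert_allclose(eigen_timescales(net), 0.05, atol=1e-12)

    def test_cluster_has_slow_emergent_mode(self):
        net = build_cluster_network(1, neurons_per_node=100, tau=0.05, seed=0)
        ts = eigen_timescales(net)
        assert ts[0] >= 10 * 0.05

    def test_feedforward_chain_keeps_node_timescale(self):
        # chain 0 -> 1 -> 2 of single nodes: strictly triangular W keeps all
        # drift eigenvalues at -1/tau
        w = np.zeros((3, 3))
        w[1, 0] = w[2, 1] = 0.9
        net = ContinuousNetwork(W=w, tau=0.05)
        np.testing.assert_allclose(eigen_timescales(net), 0.05, atol=1e-12)

    def test_excitation_monotonically_slows(self):
        base = build_cluster_network(1, neurons_per_node=50, seed=4,
                                     cluster_spectral_abscissa=0.5)
        prev = 0.0
        for scale in (1.0, 1.5, 1.9):
            net = ContinuousNetwork(W=base.W * scale, tau=base.tau)
            ts = eigen_timescales(net)[0]
            assert ts > prev
            prev = ts

    def test_node_average_shapes_and_linearity(self, rng):
        net = build_cluster_network(3, neurons_per_node=10, seed=5)
        x = rng.standard_normal((40, 30))
        avg = node_average(x, net)
        assert avg.shape == (40, 3)
        np.testing.assert_allclose(node_average(3.0 * x, net), 3.0 * avg, atol=1e-12)
        same = np.tile(x[:, :1], (1, 30))
        np.testing.assert_allclose(node_average(same, net), np.tile(x[:, :1], (1, 3)))


class TestDiscretizationGCConsistency:
    def test_population_gc_matches_long_simulation(self):
        """GC of the exactly discretized model equals GC estimated from a long
        simulated series at the same sampling step."""
        net = feedforward_two_node_network(1.0, weight=0.9)
        dv = discretize_ou(net, 0.75)
        pop = population_gc_matrices(dv, with_pc=False)
        scan = RegionalScan(data=simulate_var(dv, 40000, seed=8), tr=0.75)
        emp = gc_matrices(scan, 1, with_pc=False)
        np.testing.assert_allclose(emp.dgc, pop.dgc, atol=0.01)
        np.testing.assert_allclose(emp.igc, pop.igc, atol=0.01)


class TestCohort:
    def test_deterministic_cohort_without_variability(self):
        net_a, net_b = default_condition_pair()
        spec = CohortSpec(
            n_subjects=3, conditions=[("a", net_a), ("b", net_b)],
            between_subject_sd=0.0, score_noise_sd=0.0,
            behavior_loadings=np.array([[1.0, 0.0, 0.0, 0.0]]),
            n_timepoints=50, seed=0,
        )
        scans, scores, truth = generate_cohort(spec)
        assert np.all(truth["traits"] == 0.0)
        assert np.all(scores.to_numpy() == 0.0)

    def test_cohort_scans_roundtrip_schema(self, tmp_path):
        from slowgc import read_scan, write_scan

        net_a, net_b = default_condition_pair()
        spec = CohortSpec(n_subjects=2, conditions=[("a", net_a), ("b", net_b)],
                          n_timepoints=60, seed=1)
        scans, _, _ = generate_cohort(spec)
        assert len(scans) == 4
        for s in scans[:2]:
            assert s.n_timepoints == 60 and s.tr == 0.75
            path = tmp_path / f"{s.subject_id}_{s.condition}.tsv"
            write_scan(s, path)
            back = read_scan(path, tr=s.tr)
            np.testing.assert_allclose(back.data, s.data, atol=1e-10)

    def test_seed_reproducibility(self):
        net_a, net_b = default_condition_pair()
        spec = dict(n_subjects=2, conditions=[("a", net_a), ("b", net_b)],
                    between_subject_sd=0.1, n_timepoints=40, seed=7)
        s1, _, t1 = generate_cohort(CohortSpec(**spec))
        s2, _, t2 = generate_cohort(CohortSpec(**spec))
        np.testing.assert_array_equal(t1["traits"], t2["traits"])
        np.testing.assert_array_equal(s1[0].data, s2[0].data)

    def test_latency_shift_preserves_relative_latencies(self):
        net_a, _ = default_condition_pair()
        mean_lat = np.array([2.0, 3.0, 4.0, 3.5, 2.5])
        spec = CohortSpec(n_subjects=5, conditions=[("a", net_a)],
                          latency_sd=0.5, mean_latency=mean_lat,
                          n_timepoints=30, seed=3)
        _, _, truth = generate_cohort(spec)
        lat = truth["latencies"]
        assert np.all(lat > 0)
        diffs = lat - lat[:, :1]
        for s in range(5):
            np.testing.assert_allclose(diffs[s], mean_lat - mean_lat[0], atol=1e-12)
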
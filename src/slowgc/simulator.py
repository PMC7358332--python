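"""Ground-truth network simulator: linear (vector Ornstein-Uhlenbeck) neural
dynamics, exact discretization, hemodynamic convolution, and synthetic cohorts.

The latent dynamics follow

    tau dr/dt = -r + W r + eps,    eps ~ N(0, Sigma),

i.e. a vector OU process with drift A = (1/tau)(W - I). The process is
discretized exactly at a step D via the matrix exponential,

    A(D) = exp(D A),    Sigma(D) = G(0) - exp(D A) G(0) exp(D A)',

where G(0) solves the continuous-time Lyapunov equation
A G(0) + G(0) A' + Sigma = 0. BOLD-like observables are produced by causal
convolution with a canonical double-gamma hemodynamic response function (HRF)
with controllable per-node onset latency, followed by decimation to the scan
repetition time.

Recurrent, net-excitatory random connectivity pushes drift eigenvalues toward
zero, creating emergent timescales far slower than the single-unit time
constant; this is what makes lag-based connectivity recoverable at
second-scale sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .gc_core import VARModel, gc_matrices, stationary_cov_var
from .io_qc import RegionalScan

__all__ = [
    "ContinuousNetwork",
    "HRFSpec",
    "CohortSpec",
    "discretize_ou",
    "discretized_noise_intensity",
    "solve_lyapunov_continuous",
    "simulate_var",
    "hrf_kernel",
    "neural_to_bold",
    "build_cluster_network",
    "node_average",
    "eigen_timescales",
    "two_node_experiment",
    "cluster_pair_experiment",
    "generate_cohort",
    "feedforward_two_node_network",
    "two_timescale_network_pair",
    "default_condition_pair",
    "default_behavior_cohort",
]

MAX_BURN_IN = 100_000


@dataclass
class ContinuousNetwork:
    """A stable vector OU network: tau dr/dt = -r + W r + eps.

    ``tau`` may be a scalar (shared time constant, seconds) or a per-node
    vector. ``node_of_neuron`` maps units to coarse nodes for cluster
    networks; ``hrf_latency`` optionally stores per-node HRF onsets.
    """

    W: np.ndarray
    tau: float | np.ndarray = 1.0
    Sigma: np.ndarray | None = None
    node_of_neuron: np.ndarray | None = None
    hrf_latency: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if self.Sigma is None:
            self.Sigma = np.eye(n)
        self.Sigma = np.asarray(self.Sigma, float)
        self.tau = np.broadcast_to(np.asarray(self.tau, float), (n,)).copy()
        if np.any(self.tau <= 0):
            raise ValueError("time constants must be positive")
        lam = np.linalg.eigvals(self.drift)
        if np.max(lam.real) >= 0:
            raise ValueError(
                f"unstable network: max Re(eig(A)) = {np.max(lam.real):.4g} >= 0"
            )

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    @property
    def drift(self) -> np.ndarray:
        """A = diag(1/tau) (W - I)."""
        return (self.W - np.eye(self.n_units)) / self.tau[:, None]


@dataclass
class HRFSpec:
    """Canonical double-gamma HRF with an onset latency.

    Defaults follow the widely used canonical parameterization: response peak
    ~5 s after onset, undershoot peaking ~15 s, peak:undershoot ratio 6,
    kernel truncated at ``length`` seconds past onset. The kernel is
    normalized to unit sum.
    """

    onset_latency: float = 0.0  # seconds
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length: float = 32.0
    kernel_dt: float = 0.05

    def __post_init__(self) -> None:
        if self.onset_latency < 0:
            raise ValueError("onset latency must be nonnegative")


def solve_lyapunov_continuous(net: ContinuousNetwork) -> np.ndarray:
    """Stationary covariance G(0): solves A G(0) + G(0) A' + Sigma = 0."""
    g0 = scipy.linalg.solve_continuous_lyapunov(net.drift, -net.Sigma)
    return 0.5 * (g0 + g0.T)


def discretize_ou(net: ContinuousNetwork, delta: float) -> VARModel:
    """Exact discretization of the OU network at step ``delta`` seconds.

    Returns a VAR(1) with coefficient exp(delta A) and residual covariance
    G(0) - exp(delta A) G(0) exp(delta A)'. With this (unscaled) noise the
    stationary covariance of the discrete process equals G(0) of the
    continuous one at every delta; the conventionally 1/delta-scaled noise
    intensity is available from :func:`discretized_noise_intensity`.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    a_d = scipy.linalg.expm(delta * net.drift)
    if not np.isfinite(a_d).all():
        raise FloatingPointError("non-finite matrix exponential")
    g0 = solve_lyapunov_continuous(net)
    sig = g0 - a_d @ g0 @ a_d.T
    return VARModel(order=1, coeffs=[a_d], resid_cov=0.5 * (sig + sig.T), n_obs=0)


def discretized_noise_intensity(net: ContinuousNetwork, delta: float) -> np.ndarray:
    """The 1/delta-scaled discrete noise intensity Sigma(D)."""
    return discretize_ou(net, delta).resid_cov / delta


def _innovation_factor(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sigma)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_var(model: VARModel, n_timepoints: int, seed=None) -> np.ndarray:
    """Simulate a stable VAR with Gaussian innovations; returns (T, R).

    A burn-in of ``10 / (1 - spectral radius)`` steps (capped) is discarded so
    the returned series is approximately stationary. ``seed`` may be an int or
    a :class:`numpy.random.Generator`.
    """
    rho = float(np.max(np.abs(np.linalg.eigvals(model.companion()))))
    if rho >= 1.0:
        raise ValueError(f"unstable VAR (spectral radius {rho:.4f}); cannot simulate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = min(int(math.ceil(10.0 / (1.0 - rho))), MAX_BURN_IN)
    r, p = model.n_regions, model.order
    chol = _innovation_factor(model.resid_cov)
    total = n_timepoints + burn + p
    eps = rng.standard_normal((total, r)) @ chol.T
    x = np.zeros((total, r))
    coeffs = model.coeffs
    for t in range(p, total):
        acc = eps[t]
        for k in range(p):
            acc = acc + coeffs[k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn + p :]


def hrf_kernel(spec: HRFSpec) -> np.ndarray:
    """Sampled double-gamma HRF, onset-shifted and normalized to unit sum.

    The kernel spans ``onset_latency + length`` seconds so that changing the
    latency shifts the kernel without truncating its tail.
    """
    dt = spec.kernel_dt
    n = int(round((spec.onset_latency + spec.length) / dt))
    t = np.arange(n) * dt
    u = t - spec.onset_latency
    pos = u >= 0
    h = np.zeros(n)
    a1 = spec.peak_delay / spec.peak_dispersion
    a2 = spec.undershoot_delay / spec.undershoot_dispersion
    h[pos] = scipy.stats.gamma.pdf(u[pos], a=a1, scale=spec.peak_dispersion) - (
        scipy.stats.gamma.pdf(u[pos], a=a2, scale=spec.undershoot_dispersion)
        / spec.peak_undershoot_ratio
    )
    s = h.sum()
    if s <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return h / s


def neural_to_bold(
    series: np.ndarray,
    specs,
    sim_dt: float,
    tr_out: float,
    tr: float | None = None,
    **scan_meta,
) -> RegionalScan:
    """Convolve latent series with per-node HRFs and decimate to ``tr_out``.

    Convolution is causal (output at t uses inputs at times <= t); the initial
    transient of one kernel length is discarded before decimation.
    """
    series = np.asarray(series, float)
    t_in, n = series.shape
    if np.isscalar(specs) or isinstance(specs, HRFSpec):
        specs = [specs] * n
    if len(specs) != n:
        raise ValueError(f"{len(specs)} HRF specs for {n} nodes")
    step_f = tr_out / sim_dt
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError("sim_dt must divide tr_out")
    kernels = []
    for sp in specs:
        if abs(sp.kernel_dt - sim_dt) > 1e-12:
            sp = HRFSpec(**{**sp.__dict__, "kernel_dt": sim_dt})
        kernels.append(hrf_kernel(sp))
    n_trans = max(len(k) for k in kernels)
    out = np.empty_like(series)
    for c, k in enumerate(kernels):
        out[:, c] = np.convolve(series[:, c], k)[:t_in]
    out = out[n_trans:]
    if len(out) < step:
        raise ValueError("series too short after discarding the HRF transient")
    return RegionalScan(data=out[::step], tr=tr_out, **scan_meta)


# ---------------------------------------------------------------------------
# network constructors


def feedforward_two_node_network(
    timescale: float, weight: float = 0.9, sigma: np.ndarray | None = None
) -> ContinuousNetwork:
    """Two nodes with a single feedforward connection 0 -> 1 of the given weight."""
    w = np.zeros((2, 2))
    w[1, 0] = weight
    return ContinuousNetwork(W=w, tau=timescale, Sigma=sigma)


def build_cluster_network(
    n_nodes: int,
    neurons_per_node: int = 100,
    conn_prob: float = 0.1,
    e_weight: float = 0.08,
    i_weight: float = -0.06,
    e_fraction: float = 0.8,
    inter_node_fraction: float = 0.05,
    inter_edges: list[tuple[int, int, int]] | None = None,
    inter_weight: float = 0.1,
    tau: float = 0.05,
    cluster_spectral_abscissa: float = 0.975,
    clone_clusters: bool = False,
    seed=None,
    max_retries: int = 100,
) -> ContinuousNetwork:
    """Random sparse E/I clusters with sparse designated internode projections.

    Each node is a cluster of ``neurons_per_node`` units with random
    excitatory/inhibitory connectivity (connection probability ``conn_prob``;
    a unit's sign follows its type, E or I, with ``e_fraction`` excitatory).
    Each cluster's weights are rescaled so its leading eigenvalue sits at
    ``cluster_spectral_abscissa`` (< 1), giving a slow emergent timescale of
    tau / (1 - abscissa) despite the fast unit time constant.

    ``inter_edges`` lists (src_node, dst_node, sign) connections; only the
    designated ``inter_node_fraction`` subset of units in each node carries
    them (the same subset sends and receives, so an excitatory edge and an
    inhibitory edge between two nodes form an exactly antisymmetric coupling
    block), each unit-to-unit weight being ``sign * inter_weight``.

    ``clone_clusters`` gives every node an identical copy of one sampled
    intra-cluster weight block, making "precisely balanced" feedback motifs
    exactly symmetric (for an antisymmetric +/- edge pair the stationary
    zero-lag cross-covariance between the node averages then cancels).

    If the assembled drift matrix is unstable the intra-node connectivity is
    resampled (up to ``max_retries``; retry count in ``net.meta``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inter_edges = inter_edges or []
    npn = neurons_per_node
    n_e = int(round(e_fraction * npn))
    n_inter = max(1, int(math.ceil(inter_node_fraction * npn)))
    n_total = n_nodes * npn
    node_of = np.repeat(np.arange(n_nodes), npn)

    for attempt in range(max_retries):
        w = np.zeros((n_total, n_total))
        ok = True
        shared_block = None
        for node in range(n_nodes):
            if clone_clusters and shared_block is not None:
                w[node * npn : (node + 1) * npn,
                  node * npn : (node + 1) * npn] = shared_block
                continue
            base = node * npn
            mask = rng.random((npn, npn)) < conn_prob
            np.fill_diagonal(mask, False)
            signs = np.where(np.arange(npn) < n_e, e_weight, i_weight)
            block = mask * signs[None, :]  # column = presynaptic unit
            lam = np.max(np.linalg.eigvals(block).real)
            if lam <= 1e-6:
                ok = False
                break
            block = block * cluster_spectral_abscissa / lam
            w[base : base + npn, base : base + npn] = block
            shared_block = block
        if not ok:
            continue
        for src, dst, sign in inter_edges:
            src_units = src * npn + np.arange(n_inter)  # designated (E) subset
            dst_units = dst * npn + np.arange(n_inter)
            w[np.ix_(dst_units, src_units)] = np.sign(sign) * inter_weight
        if np.max(np.linalg.eigvals(w).real) < 1.0 - 1e-9:
            return ContinuousNetwork(
                W=w, tau=tau, node_of_neuron=node_of,
                meta={
                    "retries": attempt,
                    "n_inter": n_inter,
                    "params": dict(
                        conn_prob=conn_prob, e_weight=e_weight, i_weight=i_weight,
                        e_fraction=e_fraction, inter_weight=inter_weight,
                        cluster_spectral_abscissa=cluster_spectral_abscissa,
                    ),
                },
            )
    raise RuntimeError(f"no stable cluster network found in {max_retries} attempts")


def node_average(series: np.ndarray, net: ContinuousNetwork) -> np.ndarray:
    """Average unit time series within each node of a cluster network."""
    if net.node_of_neuron is None:
        raise ValueError("network has no unit-to-node mapping")
    nodes = np.unique(net.node_of_neuron)
    return np.column_stack(
        [series[:, net.node_of_neuron == k].mean(axis=1) for k in nodes]
    )


def eigen_timescales(net: ContinuousNetwork, subset=None) -> np.ndarray:
    """Timescales -1/Re(lambda) of the (sub-)drift matrix, sorted descending.

    ``subset`` restricts to a set of unit indices (the isolated subnetwork's
    drift is the corresponding submatrix of A, since -I/tau is diagonal).
    """
    a = net.drift
    if subset is not None:
        subset = np.asarray(subset)
        a = a[np.ix_(subset, subset)]
    lam = np.linalg.eigvals(a)
    if np.max(lam.real) >= 0:
        raise ValueError("subnetwork drift is unstable; timescales undefined")
    return np.sort(-1.0 / lam.real)[::-1]


# ---------------------------------------------------------------------------
# experiment protocols


def two_node_experiment(
    timescale: float,
    sampling_intervals,
    n_timepoints: int = 200,
    reps: int = 25,
    weight: float = 0.9,
    use_hrf: bool = True,
    hrf_onset: float = 3.0,
    sim_dt: float = 0.005,
    order: int | str = "aic",
    p_max: int = 8,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Connectivity recovery sweep for a two-node feedforward network.

    For each sampling interval, the network is simulated ``reps`` times
    (``n_timepoints`` samples each; exact 5 ms discretization, optional HRF
    convolution, then decimation), iGC / dGC / PC are estimated, and each
    connection's significance is assessed against phase-scrambling surrogates
    with Benjamini-Hochberg correction across the entries of each measure.

    The model order is selected per repetition by AIC (``order="aic"``, up to
    ``p_max``); hemodynamic convolution turns the latent VAR(1) into a
    moving-average process for which the best AR approximation needs several
    lags. The surrogates reuse the order selected on the observed data. Pass
    an integer to fix the order instead.

    Returns a tidy frame with columns interval, rep, measure, connection,
    value, p, significant. Connections are labelled ``0->1`` (the true
    direction), ``1->0``, and ``0-1`` for the symmetric measures.
    """
    from .feature_selection import phase_scramble

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = feedforward_two_node_network(timescale, weight)
    intervals = list(sampling_intervals)
    rows = []
    for rep in range(reps):
        if use_hrf:
            max_iv = max(intervals)
            steps = {iv: int(round(iv / sim_dt)) for iv in intervals}
            for iv, st in steps.items():
                if abs(iv / sim_dt - st) > 1e-9:
                    raise ValueError(f"sampling interval {iv} not a multiple of sim_dt")
            spec = HRFSpec(onset_latency=hrf_onset, kernel_dt=sim_dt)
            klen = len(hrf_kernel(spec))
            t_sim = n_timepoints * steps[max_iv] + klen + 1
            neural = simulate_var(discretize_ou(net, sim_dt), t_sim, rng)
            # convolve once at 5 ms, then decimate for each interval
            conv = np.empty_like(neural)
            k = hrf_kernel(spec)
            for c in range(2):
                conv[:, c] = np.convolve(neural[:, c], k)[: len(neural)]
            conv = conv[klen:]
            sampled = {iv: conv[:: steps[iv]][:n_timepoints] for iv in intervals}
        else:
            sampled = {
                iv: simulate_var(discretize_ou(net, iv), n_timepoints, rng)
                for iv in intervals
            }
        for iv in intervals:
            data = sampled[iv]
            if order == "aic":
                from .gc_core import select_order_aic

                p = select_order_aic(RegionalScan(data=data, tr=iv), p_max)
            else:
                p = int(order)
            obs = _two_node_measures(data, iv, p)
            null = np.empty((n_surrogates, len(obs)))
            for s in range(n_surrogates):
                surro = np.column_stack(
                    [phase_scramble(data[:, c], rng) for c in range(2)]
                )
                null[s] = _two_node_measures(surro, iv, p)
            pvals = (1.0 + (null >= np.asarray(obs)).sum(axis=0)) / (n_surrogates + 1.0)
            labels = ["0->1", "1->0", "0-1", "0-1"]
            measures = ["dgc", "dgc", "igc", "pc"]
            sig = np.zeros(len(obs), bool)
            for m in ("dgc", "igc", "pc"):
                idx = [q for q, mm in enumerate(measures) if mm == m]
                sig[idx] = multipletests(pvals[idx], alpha=alpha, method="fdr_bh")[0]
            for q in range(len(obs)):
                rows.append(
                    dict(interval=iv, rep=rep, measure=measures[q],
                         connection=labels[q], value=obs[q], p=pvals[q],
                         significant=bool(sig[q]))
                )
    return pd.DataFrame(rows)


def _two_node_measures(data: np.ndarray, tr: float, order: int):
    scan = RegionalScan(data=data, tr=tr)
    gc = gc_matrices(scan, order)
    # |PC| is tested two-sidedly via its magnitude
    return [gc.dgc[1, 0], gc.dgc[0, 1], gc.igc[0, 1], abs(gc.pc[0, 1])]


def cluster_pair_experiment(
    inter_edges: list[tuple[int, int, int]],
    n_timepoints: int = 200,
    reps: int = 10,
    tr: float = 0.75,
    sim_dt: float = 0.005,
    hrf_onset: float = 3.0,
    p_max: int = 8,
    n_surrogates: int = 200,
    inter_weight: float = 0.1,
    cluster_spectral_abscissa: float = 0.975,
    clone_clusters: bool = False,
    seed=None,
) -> pd.DataFrame:
    """Connectivity recovery for a two-cluster (2 x 100 neuron) network motif.

    Builds two random E/I clusters joined by ``inter_edges`` (e.g.
    ``[(0, 1, +1)]`` feedforward, ``[(0, 1, +1), (1, 0, -1)]`` balanced E-I
    feedback), simulates ``reps`` repetitions at 5 ms, node-averages,
    convolves with the HRF and samples at ``tr``. iGC/dGC/PC are averaged
    across repetitions and tested against phase-scrambling surrogate averages
    (one scramble per repetition per surrogate), Benjamini-Hochberg corrected
    within each measure.

    Returns one row per (measure, connection) with the rep-averaged value and
    its surrogate p value.
    """
    from .feature_selection import phase_scramble
    from .gc_core import select_order_aic

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = build_cluster_network(
        2, inter_edges=inter_edges, inter_weight=inter_weight,
        cluster_spectral_abscissa=cluster_spectral_abscissa,
        clone_clusters=clone_clusters, seed=rng,
    )
    step = int(round(tr / sim_dt))
    spec = HRFSpec(onset_latency=hrf_onset, kernel_dt=sim_dt)
    kern = hrf_kernel(spec)
    dvar = discretize_ou(net, sim_dt)
    datas, orders = [], []
    for _ in range(reps):
        neural = simulate_var(dvar, n_timepoints * step + len(kern) + 1, rng)
        nodes = node_average(neural, net)
        conv = np.column_stack(
            [np.convolve(nodes[:, c], kern)[: len(nodes)] for c in range(2)]
        )[len(kern):]
        data = conv[::step][:n_timepoints]
        datas.append(data)
        orders.append(select_order_aic(RegionalScan(data=data, tr=tr), p_max))
    p = max(set(orders), key=orders.count)  # modal AIC order across reps

    def measures(d):
        return np.asarray(_two_node_measures(d, tr, p))

    obs = np.mean([measures(d) for d in datas], axis=0)
    null = np.empty((n_surrogates, len(obs)))
    for s in range(n_surrogates):
        null[s] = np.mean(
            [
                measures(np.column_stack(
                    [phase_scramble(d[:, c], rng) for c in range(2)]
                ))
                for d in datas
            ],
            axis=0,
        )
    pvals = (1.0 + (null >= obs).sum(axis=0)) / (n_surrogates + 1.0)
    measures_lbl = ["dgc", "dgc", "igc", "pc"]
    conn_lbl = ["0->1", "1->0", "0-1", "0-1"]
    sig = np.zeros(len(obs), bool)
    for m in ("dgc", "igc", "pc"):
        idx = [q for q, mm in enumerate(measures_lbl) if mm == m]
        sig[idx] = multipletests(pvals[idx], alpha=0.05, method="fdr_bh")[0]
    return pd.DataFrame(
        dict(measure=measures_lbl, connection=conn_lbl, value=obs, p=pvals,
             significant=sig, order=p)
    )


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass
class CohortSpec:
    """Specification of a multi-subject, multi-condition synthetic cohort.

    Each subject carries a trait vector of Gaussian weight perturbations
    (SD ``between_subject_sd``) applied to the nonzero off-diagonal weights of
    every condition network (resampled until all perturbed networks are
    stable), and a scalar HRF-onset shift (SD ``latency_sd``) added to the
    per-node mean latencies -- shifting all nodes together so relative
    latencies are preserved, truncated to positive values by rejection.
    Behavioral scores are ``loadings @ trait + N(0, score_noise_sd)``.
    """

    n_subjects: int
    conditions: list[tuple[str, ContinuousNetwork]]
    between_subject_sd: float = 0.05
    latency_sd: float = 0.0
    mean_latency: float | np.ndarray = 3.0
    behavior_loadings: np.ndarray | None = None
    score_names: list[str] | None = None
    score_noise_sd: float = 0.0
    tr: float = 0.75
    n_timepoints: int = 200
    sim_dt: float = 0.05
    n_runs: int = 1
    seed: int = 0
    max_stability_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not self.conditions:
            raise ValueError("cohort needs at least one subject and one condition")
        n_nodes = {net.n_units for _, net in self.conditions}
        if len(n_nodes) != 1:
            raise ValueError("all condition networks must share the node count")
        if self.behavior_loadings is not None:
            self.behavior_loadings = np.atleast_2d(
                np.asarray(self.behavior_loadings, float)
            )


def _perturb_positions(conditions) -> list[tuple[int, int]]:
    """Union of nonzero off-diagonal weight positions across conditions."""
    pos = set()
    for _, net in conditions:
        r, c = np.nonzero(net.W)
        pos |= {(i, j) for i, j in zip(r.tolist(), c.tolist()) if i != j}
    return sorted(pos)


def generate_cohort(spec: CohortSpec):
    """Generate scans, behavioral scores, and the ground-truth record.

    Returns ``(scans, score_table, truth)`` where ``scans`` is a flat list of
    :class:`RegionalScan` (one per subject x condition x run, labelled in
    metadata), ``score_table`` a subjects x scores DataFrame (or None), and
    ``truth`` a dict with every sampled quantity needed to reproduce or audit
    the cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = spec.conditions[0][1].n_units
    positions = _perturb_positions(spec.conditions)
    mean_lat = np.broadcast_to(
        np.asarray(spec.mean_latency, float), (n_nodes,)
    ).copy()

    scans: list[RegionalScan] = []
    traits = np.zeros((spec.n_subjects, len(positions)))
    latencies = np.zeros((spec.n_subjects, n_nodes))
    subject_nets: list[dict[str, ContinuousNetwork]] = []

    for s in range(spec.n_subjects):
        # subject trait: perturbation of the nonzero weights, shared across
        # conditions, resampled until every condition network stays stable
        for _ in range(spec.max_stability_retries):
            eps = (
                rng.standard_normal(len(positions)) * spec.between_subject_sd
                if spec.between_subject_sd > 0
                else np.zeros(len(positions))
            )
            nets = {}
            try:
                for label, net in spec.conditions:
                    w = net.W.copy()
                    for val, (i, j) in zip(eps, positions):
                        if net.W[i, j] != 0.0:
                            w[i, j] += val
                    nets[label] = ContinuousNetwork(
                        W=w, tau=net.tau, Sigma=net.Sigma,
                        node_of_neuron=net.node_of_neuron,
                    )
            except ValueError:
                continue
            break
        else:
            raise RuntimeError("could not find stable perturbed networks")
        traits[s] = eps
        subject_nets.append(nets)

        # common latency shift preserves relative latencies within subject
        for _ in range(spec.max_stability_retries):
            shift = rng.standard_normal() * spec.latency_sd if spec.latency_sd else 0.0
            lat = mean_lat + shift
            if np.all(lat > 0):
                break
        else:
            raise RuntimeError("could not sample positive HRF latencies")
        latencies[s] = lat
        specs = [
            HRFSpec(onset_latency=float(l), kernel_dt=spec.sim_dt) for l in lat
        ]

        step = int(round(spec.tr / spec.sim_dt))
        klen = len(hrf_kernel(specs[int(np.argmax(lat))]))
        t_sim = spec.n_timepoints * step + klen + 1
        for label, net in nets.items():
            dvar = discretize_ou(net, spec.sim_dt)
            for run in range(spec.n_runs):
                neural = simulate_var(dvar, t_sim, rng)
                scan = neural_to_bold(
                    neural, specs, spec.sim_dt, spec.tr,
                    subject_id=f"S{s:04d}", condition=label, run=f"run{run + 1}",
                )
                scans.append(
                    scan.with_data(
                        scan.data[: spec.n_timepoints],
                        subject_id=f"S{s:04d}", condition=label,
                        run=f"run{run + 1}",
                    )
                )

    score_table = None
    if spec.behavior_loadings is not None:
        n_scores = spec.behavior_loadings.shape[0]
        if spec.behavior_loadings.shape[1] != len(positions):
            raise ValueError(
                f"loadings expect {spec.behavior_loadings.shape[1]} trait entries, "
                f"cohort has {len(positions)}"
            )
        noise = rng.standard_normal((spec.n_subjects, n_scores)) * spec.score_noise_sd
        vals = traits @ spec.behavior_loadings.T + noise
        names = spec.score_names or [f"score_{k}" for k in range(n_scores)]
        score_table = pd.DataFrame(
            vals, columns=names,
            index=[f"S{s:04d}" for s in range(spec.n_subjects)],
        )

    truth = {
        "seed": spec.seed,
        "perturbed_positions": positions,
        "traits": traits,
        "latencies": latencies,
        "condition_weights": {lbl: net.W for lbl, net in spec.conditions},
        "loadings": spec.behavior_loadings,
    }
    return scans, score_table, truth


# ---------------------------------------------------------------------------
# canonical synthetic study networks


def two_timescale_network_pair(weight: float = 0.9):
    """Two six-node networks, each with a fast and a slow subnetwork.

    Nodes 0-2 have a 50 ms time constant, nodes 3-5 a 1000 ms one. The two
    configurations differ in one fast connection (0->1 vs 0->2) and one slow
    connection (3->4 vs 3->5); lag-based connectivity should discriminate the
    slow difference and instantaneous connectivity the fast one when sampled
    at second-scale intervals.
    """
    tau = np.array([0.05, 0.05, 0.05, 1.0, 1.0, 1.0])

    def build(fast_dst, slow_dst):
        w = np.zeros((6, 6))
        w[fast_dst, 0] = weight
        w[slow_dst, 3] = weight
        return ContinuousNetwork(W=w, tau=tau)

    return build(1, 4), build(2, 5)


def default_behavior_cohort(n_subjects: int = 40, seed: int = 21) -> CohortSpec:
    """Cohort specification for the behavior-prediction study conditions.

    Two slow conditions (see :func:`default_condition_pair`), two runs of 400
    timepoints each, between-subject weight SD 0.2 (large enough that the
    inter-individual connectivity signal survives estimation noise at this
    scan length), two scores loaded on the trait entries expressed in
    condition "a" (its two nonzero edges) and two pure-noise scores.
    """
    net_a, net_b = default_condition_pair()
    # trait entries (sorted nonzero positions): (1,0), (2,0), (3,1), (3,2);
    # condition "a" expresses entries 0 and 3
    loadings = np.array([
        [1.0, 0.0, 0.0, 1.0],
        [-1.0, 0.0, 0.0, 1.0],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return CohortSpec(
        n_subjects=n_subjects,
        conditions=[("a", net_a), ("b", net_b)],
        between_subject_sd=0.2,
        behavior_loadings=loadings,
        score_names=["loaded_sum", "loaded_diff", "unloaded_1", "unloaded_2"],
        score_noise_sd=0.05,
        n_timepoints=400,
        n_runs=2,
        seed=seed,
    )


def default_condition_pair(n_nodes: int = 5, timescale: float = 1.0,
                           weight: float = 0.9):
    """Two slow node-level networks differing in their directed edge pattern.

    Condition "a" has edges 0->1 and 2->3; condition "b" has 0->2 and 1->3.
    All nodes share the given slow time constant, so the between-condition
    difference lives in the lagged structure recoverable at fMRI sampling.
    """
    def build(edges):
        w = np.zeros((n_nodes, n_nodes))
        for src, dst in edges:
            w[dst, src] = weight
        return ContinuousNetwork(W=w, tau=timescale)

    return build([(0, 1), (2, 3)]), build([(0, 2), (1, 3)])
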
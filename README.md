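# slowgc

Granger–Geweke functional connectivity for slowly sampled regional time
series: estimation, simulation, condition decoding, core-connection
selection, and behavioral-score prediction.

## The problem

Functional MRI samples brain activity every ~0.7 s, orders of magnitude
slower than neuronal dynamics. Lag-based (directed) connectivity measures
were long assumed hopeless at that rate. `slowgc` implements the full
analysis chain showing that they are not: recurrent, net-excitatory network
connectivity creates *emergent* timescales of seconds — eigenmodes of the
drift matrix with real parts near zero — and interactions at those
timescales are recoverable by directed Granger–Geweke causality (GC) at fMRI
sampling rates. The package is aimed at researchers analyzing regional BOLD
time series (and at methodologists probing when lag-based connectivity can
be trusted).

## The measures

Regions are modelled jointly as a vector autoregression (VAR) of order *p*
(AIC-selected, segment-aware so lagged pairs never span splice junctions).
For a region pair (*x*, *y*) conditioned on the remaining regions *z*, the
total conditional linear dependence decomposes additively (Geweke):

    F_{x,y|z} = F_{x→y|z} + F_{y→x|z} + F_{x∘y|z}

* **dGC** `F_{x→y|z} = ln( var(y | past of y,z) / var(y | past of x,y,z) )`
  — directed, lag-based influence;
* **iGC** `F_{x∘y|z} = ln( Σ_xx Σ_yy / det Σ_{xy} )` on the full-model
  innovation covariance Σ — instantaneous, symmetric;
* **PC** — partial correlation from the precision matrix, the zero-lag
  benchmark.

A vector Ornstein–Uhlenbeck simulator (`τ dr/dt = −r + Wr + ε`, exactly
discretized via `A(Δ) = e^{ΔA}` with `Γ(0)` from the continuous Lyapunov
equation, then convolved with a double-gamma hemodynamic response and
decimated to the scan TR) provides ground-truth networks: two-node motifs,
random excitatory/inhibitory clusters with slow emergent modes, and full
multi-subject cohorts with behavioral loadings.

Downstream modules cover ZCA / generalized-eigenvector decorrelation (purging
instantaneous correlations), linear-SVM condition decoding with
Clopper–Pearson intervals and permutation tests, two-level recursive feature
elimination with elbow detection, phase-scrambling surrogates, digraph
extraction, and leave-one-out behavioral-score prediction with
percentage-bend correlations and Benjamini–Yekutieli correction.

## Worked example

```python
import numpy as np
import slowgc as sg

# ground truth: two nodes with a slow (1 s) timescale, node 0 -> node 1
net = sg.feedforward_two_node_network(timescale=1.0, weight=0.9)

# simulate BOLD-like data: exact 5 ms discretization, HRF, 750 ms sampling
hrf = sg.HRFSpec(onset_latency=3.0, kernel_dt=0.005)
neural = sg.simulate_var(sg.discretize_ou(net, 0.005), 40_000, seed=0)
scan = sg.neural_to_bold(neural, hrf, sim_dt=0.005, tr_out=0.75)

order = sg.select_order_aic(scan, 8)
gc = sg.gc_matrices(scan, order)
print("order", order)
print("dGC 0->1 %.3f   dGC 1->0 %.3f" % (gc.dgc[1, 0], gc.dgc[0, 1]))
print("iGC %.3f   PC %.3f" % (gc.igc[0, 1], gc.pc[0, 1]))
```

Output (seed 0):

```
order 8
dGC 0->1 0.132   dGC 1->0 0.026
iGC 0.100   PC 0.470
```

The true direction carries five times more lag-based dependence
than the (spurious) reverse direction, even though the series were smoothed
by a ~6 s hemodynamic response and sampled at 750 ms — because the network's
interaction timescale (1 s) survives the slow sampling. Repeating with
`timescale=0.05` drives both dGC entries to the noise floor (0.032 / 0.021)
while iGC rises to 0.595: sub-TR interactions are visible only as
instantaneous covariance.

A thin CLI mirrors the library: `slowgc qc`, `slowgc estimate`,
`slowgc decorrelate`, `slowgc classify`.

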
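# Methods

This note documents the models, estimators, parameter defaults, and numerical
choices in `slowgc`, and what the synthetic-data tests do and do not
establish about real data.

## Conditional Granger–Geweke estimation (`gc_core`)

**Model.** Each scan's regions are fitted jointly as a VAR(p) by ordinary
least squares. Columns are demeaned per segment; lagged (predictor, response)
pairs are pooled across the scan's contiguous segments and never formed across
a segment junction — the property that makes decimation, block concatenation
and motion scrubbing safe upstream of a lag-based estimator. The residual
covariance is normalized by the pooled (effective) sample count, not the raw
scan length, so connectivity magnitudes are comparable across segmentations.
Model order is chosen by AIC over p = 1…p_max on a shared response sample
(the first p_max rows of each segment are excluded for every candidate);
ties go to the smallest order.

**Measures.** For a pair (x, y) conditioned on all remaining regions z:

* directed GC (two-stage): `F_{x→y|z} = ln(σ²_red / σ²_full)` where the
  reduced regression omits the source's past and is refitted on the data;
* instantaneous GC: `ln(Σ_xx Σ_yy / det Σ_{{x,y}})` from the full model's
  innovation covariance;
* the full measure is computed as
  `ln(σ²_red,x σ²_red,y / det Σ_{{x,y}})`, which makes the additivity
  identity `F_{x,y|z} = F_{x→y|z} + F_{y→x|z} + F_{x∘y|z}` hold exactly by
  construction, sample or population.

Sample GC values are *not* clamped at zero; a small positive bias of order
p·R/T is expected and consumers (the classifier) use raw values.

**Population oracle.** For a known VAR, all reduced regressions are solved
analytically from the autocovariance sequence (companion-form discrete
Lyapunov equation plus the Yule–Walker recursion), so population GC values
are exact and nonnegative. The **one-stage estimator** reuses this machinery
on the *fitted* full model: one data regression, reduced innovation variances
derived from the fitted model's implied autocovariances at the same order.
(The autocovariances are obtained exactly from the Lyapunov solution rather
than by truncating an iterated sum; the two agree to machine precision for
stable models.) With population inputs the one-stage and two-stage routes
coincide; on data they are strongly rank-correlated.

**Partial correlation** comes from the precision matrix of the per-segment
demeaned covariance, with an optional scalar shrinkage toward a scaled
identity for rank-deficient covariances.

## The simulator (`simulator`)

Latent dynamics are a vector Ornstein–Uhlenbeck process
`τ dr/dt = −r + W r + ε`, `ε ~ N(0, Σ)`, drift `A = (1/τ)(W − I)` (τ may be
per-node). Discretization is exact — `A(Δ) = e^{ΔA}`, noise
`Γ(0) − e^{ΔA} Γ(0) e^{ΔA'}` with `Γ(0)` from the continuous Lyapunov
equation — never Euler–Maruyama. We deliberately use the *unscaled* discrete
noise (no 1/Δ factor) inside simulation so the discrete process's stationary
covariance equals `Γ(0)` at every sampling step; the conventional
1/Δ-scaled intensity is exposed separately (`discretized_noise_intensity`).
Simulations discard a burn-in of `10/(1 − spectral radius)` steps (capped at
10⁵).

**Hemodynamics.** The HRF is the canonical double-gamma (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6, 32 s support),
normalized to unit sum, with a per-node onset latency that shifts the kernel
without truncating it. Convolution is causal; the initial kernel-length
transient is discarded before decimation to the output TR.

**Cluster networks.** Each node is a cluster of 100 units, 80% excitatory
(+0.08) / 20% inhibitory (−0.06), directed connection probability 0.1, unit
time constant 50 ms. Each cluster's weight block is rescaled so its leading
eigenvalue sits at 0.975, putting the slowest emergent timescale at
τ/(1−0.975) = 2 s — forty times the unit constant, the mechanism by which
fast units produce second-scale network dynamics. Internode connections run
only between designated 5% subsets of units; the same subset sends and
receives, with the edge's sign carried by the weight (default magnitude 0.1
per unit-to-unit connection). That choice makes a +/− feedback pair exactly
antisymmetric, which is the condition under which the stationary zero-lag
cross-covariance between node averages cancels ("balanced" feedback); the
`clone_clusters` option additionally makes the two clusters' internal
connectivity identical so the cancellation is structural rather than
approximate. The internode weight default was fixed by sweeping the
asymptotic node-level GC: stronger antisymmetric coupling creates fast
oscillatory modes that alias at 750 ms sampling and destroy both the slow
timescale and the recoverable GC, so the default sits in the slow-coupling
regime (pair timescale ≈ 1 s).

**Experiment protocols.** The two-node sweep simulates at 5 ms, convolves,
decimates to each sampling interval, estimates connectivity on 200 samples,
and assesses each connection against phase-scrambling surrogates with
Benjamini–Hochberg correction within each measure, 25 repetitions. The model
order is AIC-selected per repetition: hemodynamic convolution turns the
latent VAR(1) into a moving-average process whose best AR approximation
needs several lags — with the order pinned at 1 the directed asymmetry is
largely invisible, with AIC (typically selecting the cap of 8 on convolved
data) the slow network's true direction is detected in ~90% of repetitions
at 750 ms and the fast network's in none. The cluster-pair protocol averages
GC over 10 repetitions before testing against surrogate *averages* (one
scramble per repetition per surrogate), which is what makes the
repetition-averaged statistic testable at its own noise level.

**Cohorts.** `generate_cohort` draws one trait vector per subject — Gaussian
perturbations of the nonzero network weights, shared across conditions and
resampled until every perturbed network is stable — plus a scalar HRF-onset
shift added to all node latencies (preserving relative latencies within
subject, rejected until positive). Behavioral scores are
`loadings @ trait + noise`. The behavior study conditions
(`default_behavior_cohort`) use 40 subjects, two 400-timepoint runs per
condition averaged at the GC level, trait SD 0.2 and score noise SD 0.05:
the trait signal in a single 200-sample scan is smaller than GC estimation
noise, and run-averaging over longer scans is what brings individual
differences above the floor — itself a faithful miniature of why the original
analyses averaged two runs.

## Decorrelation (`decorrelation`)

ZCA whitening uses `C^{−1/2} = E D^{−1/2} E^T`; it is the whitening transform
closest to the identity in least squares, so region identity (and hence
cross-subject feature correspondence) is approximately preserved. Joint
decorrelation of a scan pair solves the symmetric-definite generalized
eigenproblem `C_R g = λ C_T g` (equivalently: whiten by C_T, eigendecompose
the whitened C_R), giving one projection G with `G'C_T G = I` and `G'C_R G`
diagonal. The textbook product `E_T D_T^{−1/2} E_R` of two *separate*
eigendecompositions does not jointly diagonalize in general; it is available
behind `literal_construction=True` for comparison, and a test demonstrates
its failure.

**Known limitation.** On the synthetic two-condition cohort (40 subjects,
5 regions), GC features computed from the per-subject generalized-eigenvector
projection decode conditions at chance: unlike ZCA, the per-subject
eigenbasis does not preserve cross-subject feature correspondence at this
scale, and the decorrelation-survival result is therefore established with
ZCA only. GEV's decorrelation guarantee itself (projected PC features at the
numerical noise floor) holds exactly and is tested.

## Classification (`classification`)

Linear SVM (or logistic regression) in a pipeline whose z-scoring is fitted
on training folds only. Leave-one-out and stratified 10-fold schemes;
accuracies carry exact Clopper–Pearson 95% intervals. The optional
hyperparameter protocol tunes (learner, penalty, C on a log grid 10⁻⁴…10⁴)
on each of five folds in turn and pools held-out predictions. Permutation
tests shuffle labels within subject when subject identifiers are present and
use add-one smoothing `p = (b+1)/(n+1)`. Subject-averaged classification
trains on half the subjects and classifies class-wise means of m held-out
subjects, halves exchanged.

## Feature selection (`feature_selection`)

Two-level RFE: inner level averages absolute discriminative weights over n₂
folds and discards the lowest 10% (retained = ⌈0.9·n⌉, at least one
dropped); outer level scores every retained set on each of n₁ held-out folds,
averaged over 5 fold-seed repetitions. The reported nested feature sets come
from the elimination run on the full table; the accuracy curve is fully
cross-validated. The N-way variant drops the union of each one-vs-all
learner's bottom 1%. The elbow is a constrained two-line least-squares fit on
the retained-count axis, first point excluded; the breakpoint is assigned to
the flat (high-count) segment — i.e. the elbow is the smallest retained set
whose accuracy still lies on the high-performance line — and the collapse
segment must have the strictly steeper slope; when no breakpoint satisfies
the constraint (a featureless linear curve) the last level is returned with
a warning.

Phase scrambling randomizes positive-frequency phases with conjugate
symmetry (DC untouched, Nyquist sign-flipped), preserving each series'
amplitude spectrum exactly; regions are scrambled independently because the
null must destroy cross-region dependence. The task-generic binomial test
uses p = mean selected-set size / feature count and flags features present in
at least k* sets, k* the smallest count with tail probability < α. The
digraph pipeline antisymmetrizes dGC, selects candidate connections by RFE on
one stratified fold, and Bonferroni-tests the remaining subjects' values
against per-scan surrogate nulls, keeping only the dominant significant
direction per pair.

## Behavior (`behavior`)

Per score: leave-one-out ridge regression (the ε-insensitive linear SVR is
available behind a flag), features z-scored with training statistics only.
Prediction quality is Wilcox's percentage-bend correlation (bend 0.2) with a
t-approximation p value, flagged across the battery by Benjamini–Yekutieli.
Significance is **one-sided for positive association** by default: under the
null, out-of-sample predictions are systematically anti-correlated with the
held-out scores (each fit excludes its target, shrinking predictions toward
the training mean — the null correlation centers near −0.1 at n = 40), and a
two-sided test flags those artifacts as discoveries at several times the
nominal rate. The composite-identification KS test is likewise one-sided for
the self-correlations being stochastically larger. Two-sided alternatives
remain available via flags.

## Quality control (`io_qc`)

Framewise displacement sums absolute frame-to-frame translations (mm) and
rotations converted to arc length on a 50 mm sphere (configurable; rotations
in radians). Frames with FD > 0.5 mm are scrubbed together with one neighbor
per side (use the fitted order for p > 1); surviving runs become segments.
Decimation by factor k concatenates the k interleaved subsampled series with
segment boundaries at the junctions, conserving the total sample count. The
four adequacy diagnostics: companion spectral radius (log < 0), a Ding-style
consistency statistic on the lag-0/lag-1 covariances (≥ 80%), Durbin–Watson
of the residuals in (1, 3) for > 90% of regions, and the ADF statistic below
its 5% critical value for > 90% of regions.

## Problem sizes

The test suite and `scripts/acceptance.py` run miniatures of the original
protocols: two-node sweeps with 25 repetitions × 200 timepoints and 200
phase-scrambling surrogates; one cluster pair (2 × 100 units) with 10
repetitions; cohorts of 24–40 subjects with 5–6 regions and 200–500
timepoints; 10-seed calibrations for the behavior null. These sizes were
chosen so each protocol's qualitative result is resolvable with comfortable
margin; passing them demonstrates internal correctness and the timescale
phenomenology on data the generator can produce — linear Gaussian dynamics,
a known parcellation, additive HRF variation — not performance on real BOLD
data with nonstationarity, physiological noise, or atlas misassignment.
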
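"""Selecting core connections: recursive feature elimination, elbow fitting,
task-generic binomial tests, phase-scrambling surrogates, and digraphs.

RFE retrains a linear classifier while repeatedly discarding the connections
with the lowest average absolute discriminative weight, producing an
accuracy-versus-retained-features curve whose elbow marks a minimal
high-performing connection set. Phase-scrambled surrogates preserve each
series' amplitude spectrum while destroying cross-region dependence, giving
null distributions for individual connection strengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .classification import FeatureTable, make_classifier
from .gc_core import gc_matrices
from .io_qc import RegionalScan

__all__ = [
    "RFEResult",
    "rfe_two_level",
    "rfe_nway",
    "fit_elbow",
    "binomial_task_generic",
    "phase_scramble",
    "digraph_pipeline",
    "overlap_significance",
    "antisymmetrize",
]


@dataclass
class RFEResult:
    """Accuracy-vs-retained-features curve with nested retained sets.

    ``levels[k]`` is a dict with the retained feature indices (into the input
    table), the cross-validated generalization accuracy at that level, and the
    mean absolute weight per retained feature. Sets shrink strictly and are
    nested. ``elbow_index`` indexes ``levels``.
    """

    levels: list[dict]
    elbow_index: int
    n1: int
    n2: int
    drop_fraction: float
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = [len(l["retained"]) for l in self.levels]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("retained sets must shrink strictly")
        for a, b in zip(self.levels, self.levels[1:]):
            if not set(b["retained"]) <= set(a["retained"]):
                raise ValueError("retained sets must be nested")
        if not 0 <= self.elbow_index < len(self.levels):
            raise ValueError("elbow index out of range")

    @property
    def retained_counts(self) -> np.ndarray:
        return np.array([len(l["retained"]) for l in self.levels])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([l["accuracy"] for l in self.levels])

    def elbow_features(self) -> list[int]:
        return list(self.levels[self.elbow_index]["retained"])


def _drop_count(current: int, drop_fraction: float) -> int:
    # retained = ceil((1 - f) * n); at least one feature is dropped
    return max(1, current - math.ceil((1.0 - drop_fraction) * current))


def _nway_classifier():
    from sklearn.multiclass import OneVsRestClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", OneVsRestClassifier(LinearSVC(C=1.0, max_iter=20000))),
    ])


def _fit_model(x, y, nway):
    model = (_nway_classifier() if nway else make_classifier()).fit(x, y)
    clf = model.named_steps["clf"]
    if nway:
        weights = np.vstack([np.abs(e.coef_) for e in clf.estimators_])
    else:
        weights = np.abs(clf.coef_)
    return model, weights  # weights: (n_learners, n_features)


def _clamped_kfold(n_splits, y, rng):
    counts = np.unique(y, return_counts=True)[1]
    return StratifiedKFold(
        n_splits=max(2, min(n_splits, int(counts.min()))),
        shuffle=True, random_state=int(rng.integers(2**31)),
    )


def _mean_abs_weights(x, y, cols, n2, rng, nway=False):
    """Average |coef| over n2 inner folds, each fit leaving one fold out."""
    kf = _clamped_kfold(n2, y, rng)
    acc = None
    for keep_idx, _ in kf.split(x, y):
        _, w = _fit_model(x[keep_idx][:, cols], y[keep_idx], nway)
        acc = w if acc is None else acc + w
    return acc / n2  # (n_learners, len(cols))


def _elimination_path(x, y, n2, drop_fraction, rng, per_learner_drop=None,
                      nway=False):
    """Nested retained sets from repeated weight-ranked elimination."""
    cols = list(range(x.shape[1]))
    path = []
    while cols:
        w = _mean_abs_weights(x, y, cols, n2, rng, nway)
        path.append((list(cols), w.mean(axis=0)))
        if len(cols) == 1:
            break
        if per_learner_drop is None:
            k = _drop_count(len(cols), drop_fraction)
            order = np.argsort(w.mean(axis=0), kind="stable")
            drop = {cols[i] for i in order[:k]}
        else:
            # union over one-vs-all learners of each learner's bottom fraction
            drop = set()
            for learner_w in w:
                k = max(1, math.ceil(per_learner_drop * len(cols)))
                order = np.argsort(learner_w, kind="stable")
                drop |= {cols[i] for i in order[:k]}
            if len(drop) >= len(cols):
                keep_one = cols[int(np.argmax(w.mean(axis=0)))]
                drop.discard(keep_one)
                drop = set(list(drop)[: len(cols) - 1])
        cols = [c for c in cols if c not in drop]
    return path


def _rfe(table, n1, n2, drop_fraction, seed, n_repeats, per_learner_drop, nway):
    y = table.labels
    classes = np.unique(y)
    if nway and len(classes) < 3:
        raise ValueError("N-way RFE needs >= 3 classes; use rfe_two_level")
    if not nway and len(classes) != 2:
        raise ValueError("two-level RFE needs binary labels")
    x = table.x
    rng = np.random.default_rng(seed)

    # canonical nested path from the full data defines the reported sets
    path = _elimination_path(x, y, n2, drop_fraction, np.random.default_rng(seed),
                             per_learner_drop=per_learner_drop, nway=nway)
    n_levels = len(path)

    # generalization accuracy per level: outer n1-fold CV, repeated with
    # different fold seeds and averaged
    acc = np.zeros(n_levels)
    n_eval = 0
    for rep in range(n_repeats):
        rep_rng = np.random.default_rng(seed + 1000 * (rep + 1))
        kf = _clamped_kfold(n1, y, rep_rng)
        for train, test in kf.split(x, y):
            fold_path = _elimination_path(
                x[train], y[train], n2, drop_fraction, rep_rng,
                per_learner_drop=per_learner_drop, nway=nway,
            )
            for lvl in range(n_levels):
                cols = fold_path[min(lvl, len(fold_path) - 1)][0]
                model, _ = _fit_model(x[train][:, cols], y[train], nway)
                acc[lvl] += float(
                    np.mean(model.predict(x[test][:, cols]) == y[test])
                )
            n_eval += 1
    acc /= n_eval

    levels = [
        {"retained": cols, "accuracy": float(acc[lvl]), "mean_abs_weight": w}
        for lvl, (cols, w) in enumerate(path)
    ]
    counts = np.array([len(l["retained"]) for l in levels])
    try:
        elbow = fit_elbow(counts, acc)
    except ValueError:
        elbow = len(levels) - 1
    return RFEResult(
        levels=levels, elbow_index=int(elbow), n1=n1, n2=n2,
        drop_fraction=drop_fraction, seed=seed,
        provenance={"n_repeats": n_repeats, "classes": classes.tolist(),
                    "nway": nway},
    )


def rfe_two_level(
    table: FeatureTable,
    n1: int = 10,
    n2: int = 5,
    drop_fraction: float = 0.10,
    seed: int = 0,
    n_repeats: int = 5,
) -> RFEResult:
    """Two-level recursive feature elimination for binary labels.

    Inner level: absolute discriminative weights averaged over ``n2`` folds;
    the lowest-weighted ``drop_fraction`` of features (at least one) is
    discarded and the classifier retrained, until no features remain. Outer
    level: each of ``n1`` folds is held out in turn and each level's retained
    set (re-derived on the training folds) is scored on it; level accuracies
    are averaged over folds and over ``n_repeats`` fold seeds. The reported
    nested retained sets come from the elimination run on the full table.
    """
    return _rfe(table, n1, n2, drop_fraction, seed, n_repeats,
                per_learner_drop=None, nway=False)


def rfe_nway(
    table: FeatureTable,
    n1: int = 10,
    n2: int = 5,
    drop_fraction_per_learner: float = 0.01,
    seed: int = 0,
    n_repeats: int = 5,
) -> RFEResult:
    """RFE for >= 3 classes with one-versus-all learners.

    Each level discards the union, over the one-vs-all learners, of every
    learner's lowest-weighted ``drop_fraction_per_learner`` features.
    """
    return _rfe(table, n1, n2, drop_fraction_per_learner, seed, n_repeats,
                per_learner_drop=drop_fraction_per_learner, nway=True)


def fit_elbow(retained_counts: np.ndarray, accuracies: np.ndarray) -> int:
    """Constrained two-line fit locating the elbow of an RFE curve.

    ``retained_counts`` and ``accuracies`` are per-level, in elimination order
    (counts decreasing). The candidate breakpoint e splits the curve (on the
    retained-count axis) into a flat segment (x >= e, including the
    breakpoint: the minimal set whose accuracy still sits on the
    high-performance line) and a collapse segment (x < e), each fitted by
    least squares. The collapse segment must have the steeper (larger) slope.
    The curve's first point (the full feature set) is excluded from the fit.
    Returns the level index of the breakpoint minimizing total squared
    residual; if no breakpoint satisfies the constraint, the last level is
    returned with a warning.
    """
    x = np.asarray(retained_counts, float)
    acc = np.asarray(accuracies, float)
    if len(x) < 4:
        raise ValueError("need at least four RFE levels to fit an elbow")
    if np.any(np.diff(x) >= 0):
        raise ValueError("retained counts must be strictly decreasing")
    xf, af = x[1:], acc[1:]  # first point excluded
    best, best_sse = None, np.inf
    for cand in range(len(x)):
        e = x[cand]
        high = xf >= e  # many features: flat, includes the breakpoint
        low = xf < e  # few features: collapse side
        if high.sum() < 2 or low.sum() < 2:
            continue
        s_h, sse_h = _line_fit(xf[high], af[high])
        s_l, sse_l = _line_fit(xf[low], af[low])
        if s_l <= s_h + 1e-12:  # collapse must be on the few-features side
            continue
        if sse_h + sse_l < best_sse - 1e-15:
            best, best_sse = cand, sse_h + sse_l
    if best is None:
        warnings.warn("no breakpoint satisfies the slope constraint; "
                      "returning the last level")
        return len(x) - 1
    return best


def _line_fit(x, y):
    a = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    return float(coef[0]), float(resid @ resid)


def binomial_task_generic(
    selected_sets: list[set], universe_size: int, alpha: float = 0.05
):
    """Connections selected consistently across tasks, by a binomial tail test.

    A feature's presence in each task's RFE set is treated as a Bernoulli
    trial with success probability p = (mean selected-set size) / (number of
    features). Returns the features present in at least k* sets, where k* is
    the smallest count whose binomial tail P(X >= k) falls below ``alpha``,
    together with k*.
    """
    n = len(selected_sets)
    if n < 2:
        raise ValueError("need at least two selected sets")
    sets = [set(s) for s in selected_sets]
    p = float(np.mean([len(s) for s in sets])) / universe_size
    k_star = None
    for k in range(1, n + 1):
        if scipy.stats.binom.sf(k - 1, n, p) < alpha:
            k_star = k
            break
    if k_star is None:
        return set(), None
    counts: dict = {}
    for s in sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    return {f for f, c in counts.items() if c >= k_star}, k_star


def phase_scramble(series: np.ndarray, rng=None) -> np.ndarray:
    """Phase-scrambled surrogate preserving the amplitude spectrum exactly.

    Phases of the positive-frequency bins are randomized (conjugate symmetry
    maintained; the DC bin is untouched and, for even length, the Nyquist bin
    gets a random sign), so mean and variance are preserved and cross-series
    dependence is destroyed when regions are scrambled independently.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 8:
        raise ValueError("series too short to phase-scramble")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f = np.fft.rfft(x)
    out = f.copy()
    hi = len(f) - 1 if n % 2 == 0 else len(f)
    phases = rng.uniform(0, 2 * np.pi, max(0, hi - 1))
    out[1:hi] = np.abs(f[1:hi]) * np.exp(1j * phases)
    if n % 2 == 0:
        out[-1] = f[-1] * rng.choice([-1.0, 1.0])
    return np.fft.irfft(out, n)


def antisymmetrize(m: np.ndarray) -> np.ndarray:
    return m - m.T


def digraph_pipeline(
    dgc_list: list[np.ndarray],
    scans: list[RegionalScan],
    labels,
    folds: int = 5,
    alpha: float = 0.05,
    order: int = 1,
    n_surrogates: int = 200,
    seed: int = 0,
    rfe_kwargs: dict | None = None,
):
    """Unweighted dominant-direction digraphs from dGC with surrogate testing.

    Stage 1: subjects are split into ``folds`` folds; two-level RFE on the
    first fold's antisymmetrized dGC features (binary ``labels``) selects a
    candidate connection set K, augmented with symmetric counterparts.
    Stage 2: for every scan in the remaining folds, a phase-scrambling null of
    the dGC values restricted to K sets a Bonferroni-corrected significance
    threshold (alpha / |K|); the digraph marks, for each significant pair, the
    dominant direction only.

    Returns ``(digraphs, K, rfe_result)`` where ``digraphs`` maps scan index
    to a binary R x R matrix (entry (i, j) = 1 iff j -> i is the dominant
    significant direction).
    """
    from .classification import feature_ids as fid, vectorize

    labels = np.asarray(labels)
    n = len(dgc_list)
    if n != len(scans) or n != len(labels):
        raise ValueError("dgc_list, scans and labels must align")
    r = dgc_list[0].shape[0]
    rng = np.random.default_rng(seed)
    # stratified fold assignment so every fold carries both labels
    fold_of = np.empty(n, int)
    for lbl in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == lbl))
        fold_of[idx] = np.arange(len(idx)) % folds

    # stage 1: RFE on antisymmetrized dGC of fold 0
    stage1 = np.flatnonzero(fold_of == 0)
    feats = np.array([vectorize(antisymmetrize(m), "dgc") for m in dgc_list])
    table = FeatureTable(
        x=feats[stage1], labels=labels[stage1], feature_ids=fid(r, "dgc"),
    )
    rfe = rfe_two_level(table, seed=seed, **(rfe_kwargs or {}))
    # map vector positions back to (dst, src) pairs, add symmetric counterparts
    pairs = [(i, j) for i in range(r) for j in range(r) if i != j]
    k_pairs = set()
    for f in rfe.elbow_features():
        i, j = pairs[f]
        k_pairs.add((i, j))
        k_pairs.add((j, i))
    k_sorted = sorted(k_pairs)
    if not k_sorted:
        warnings.warn("stage-1 RFE selected no features; digraphs are empty")
        return {int(i): np.zeros((r, r)) for i in np.flatnonzero(fold_of != 0)}, [], rfe

    # stage 2: per remaining scan, surrogate null for the K connections
    digraphs = {}
    thr_q = 1.0 - alpha / len(k_sorted)  # Bonferroni over |K|
    for idx in np.flatnonzero(fold_of != 0):
        scan = scans[idx]
        null = np.empty((n_surrogates, len(k_sorted)))
        for s in range(n_surrogates):
            surro = np.column_stack(
                [phase_scramble(scan.data[:, c], rng) for c in range(r)]
            )
            g = gc_matrices(scan.with_data(surro, segments=scan.segments),
                            order, with_pc=False)
            null[s] = [g.dgc[i, j] for i, j in k_sorted]
        obs = np.array([dgc_list[idx][i, j] for i, j in k_sorted])
        sig = obs > np.quantile(null, thr_q, axis=0)
        dg = np.zeros((r, r))
        seen = set()
        for q, (i, j) in enumerate(k_sorted):
            if (j, i) in seen or not sig[q]:
                continue
            rev = k_sorted.index((j, i)) if (j, i) in k_pairs else None
            if rev is not None and sig[rev]:
                # both directions significant: keep the dominant one
                if dgc_list[idx][i, j] >= dgc_list[idx][j, i]:
                    dg[i, j] = 1.0
                else:
                    dg[j, i] = 1.0
                seen.add((i, j))
                seen.add((j, i))
            else:
                dg[i, j] = 1.0
                seen.add((i, j))
        digraphs[int(idx)] = dg
    return digraphs, k_sorted, rfe


def overlap_significance(
    set_a: set, set_b: set, universe_size: int,
    n_perm: int = 1000, seed: int = 0,
) -> tuple[float, float]:
    """Permutation p value for the overlap of two connection sets.

    Observed overlap is |A intersect B| / |B|. The null preserves both set
    sizes while drawing identities uniformly from the universe; p uses
    add-one smoothing, (b + 1) / (n_perm + 1).
    Returns ``(observed_overlap, p)``.
    """
    if not set_b:
        raise ValueError("set_b must be nonempty")
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("sets cannot exceed the universe")
    rng = np.random.default_rng(seed)
    obs = len(a & b) / len(b)
    count = 0
    universe = np.arange(universe_size)
    for _ in range(n_perm):
        ra = set(rng.choice(universe, size=len(a), replace=False).tolist())
        rb = set(rng.choice(universe, size=len(b), replace=False).tolist())
        if len(ra & rb) / len(rb) >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)
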
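"""Decoding condition labels from connectivity features.

Connectivity matrices are vectorized into per-scan feature vectors (upper
triangle for symmetric measures, all off-diagonal entries for directed ones)
and fed to linear max-margin or logistic classifiers, with exact binomial
(Clopper-Pearson) confidence intervals on the cross-validated accuracy and
permutation tests against label-shuffled nulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .gc_core import GCMatrices
from .io_qc import RegionalScan

__all__ = [
    "FeatureTable",
    "CVResult",
    "vectorize",
    "unvectorize",
    "feature_ids",
    "average_runs",
    "two_way_classify",
    "nway_classify",
    "permutation_test",
    "subject_average_classify",
    "bold_baseline_features",
    "clopper_pearson",
    "make_classifier",
]


@dataclass
class FeatureTable:
    """subjects (or scans) x features matrix with aligned labels.

    Feature ordering is fixed by :func:`vectorize` and identical across rows,
    which is what lets weights be compared and features eliminated
    consistently across subjects.
    """

    x: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    subjects: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.labels = np.asarray(self.labels)
        if self.x.ndim != 2 or len(self.labels) != len(self.x):
            raise ValueError("feature matrix and labels are misaligned")
        if len(self.feature_ids) != self.x.shape[1]:
            raise ValueError("feature_ids length must equal the column count")
        if not np.isfinite(self.x).all():
            raise ValueError("feature table contains missing or non-finite values")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def to_tsv(self, path) -> None:
        """Write the table as TSV (header = feature ids) plus a JSON side-car
        with labels, subjects, and provenance."""
        import json
        from pathlib import Path

        pd.DataFrame(self.x, columns=self.feature_ids).to_csv(
            path, sep="\t", index=False
        )
        meta = {
            "labels": self.labels.tolist(),
            "subjects": None if self.subjects is None else self.subjects.tolist(),
            "provenance": self.provenance,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        import json
        from pathlib import Path

        df = pd.read_csv(path, sep="\t")
        meta = json.loads(Path(str(path) + ".json").read_text())
        subjects = meta.get("subjects")
        return cls(
            x=df.to_numpy(float), labels=np.asarray(meta["labels"]),
            feature_ids=[str(c) for c in df.columns],
            subjects=None if subjects is None else np.asarray(subjects),
            provenance=meta.get("provenance", {}),
        )

    def select(self, cols) -> "FeatureTable":
        cols = np.asarray(cols)
        return FeatureTable(
            x=self.x[:, cols], labels=self.labels,
            feature_ids=[self.feature_ids[c] for c in cols],
            subjects=self.subjects, provenance=dict(self.provenance),
        )


@dataclass
class CVResult:
    accuracy: float
    ci_low: float
    ci_high: float
    precision: float
    recall: float
    per_fold: list
    scheme: str
    n: int
    permutation_p: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.accuracy, self.ci_low, self.ci_high]
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("accuracy and CI bounds must lie in [0, 1]")
        if not self.ci_low <= self.accuracy <= self.ci_high:
            raise ValueError("CI must bracket the accuracy")


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    low = 0.0 if k == 0 else scipy.stats.beta.ppf(alpha / 2, k, n - k + 1)
    high = 1.0 if k == n else scipy.stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(low), float(high)


# ---------------------------------------------------------------------------
# feature construction


def feature_ids(n_regions: int, which: str, names=None) -> list[str]:
    names = names or [str(i) for i in range(n_regions)]
    if which in ("igc", "pc", "full"):
        return [
            f"{names[i]}-{names[j]}"
            for i in range(n_regions)
            for j in range(i + 1, n_regions)
        ]
    if which in ("dgc", "digraph"):
        return [
            f"{names[j]}->{names[i]}"  # source column j, destination row i
            for i in range(n_regions)
            for j in range(n_regions)
            if i != j
        ]
    raise ValueError(f"unknown measure {which!r}")


def vectorize(gc: GCMatrices | np.ndarray, which: str = "igc") -> np.ndarray:
    """Row-major stable vectorization of a connectivity matrix.

    Symmetric measures use the upper triangle (R(R-1)/2 features); directed
    measures use all off-diagonal entries (R^2 - R features).
    """
    m = gc if isinstance(gc, np.ndarray) else getattr(gc, which if which != "digraph" else "dgc")
    if m is None:
        raise ValueError(f"matrix {which!r} not present")
    if not np.isfinite(m).all():
        raise ValueError("connectivity matrix contains non-finite entries")
    r = m.shape[0]
    if which in ("igc", "pc", "full"):
        return m[np.triu_indices(r, k=1)]
    if which in ("dgc", "digraph"):
        mask = ~np.eye(r, dtype=bool)
        return m[mask]
    raise ValueError(f"unknown measure {which!r}")


def unvectorize(vec: np.ndarray, n_regions: int, which: str = "igc") -> np.ndarray:
    """Inverse of :func:`vectorize` (diagonal set to zero)."""
    out = np.zeros((n_regions, n_regions))
    if which in ("igc", "pc", "full"):
        iu = np.triu_indices(n_regions, k=1)
        out[iu] = vec
        out += out.T
    elif which in ("dgc", "digraph"):
        out[~np.eye(n_regions, dtype=bool)] = vec
    else:
        raise ValueError(f"unknown measure {which!r}")
    return out


def average_runs(*gcs: GCMatrices) -> GCMatrices:
    """Entrywise mean of per-run connectivity estimates."""
    if len(gcs) < 2:
        raise ValueError("need at least two runs to average")
    tags = {g.estimator_tag for g in gcs}
    if len(tags) != 1:
        raise ValueError(f"cannot average estimates from different estimators: {tags}")
    mean = lambda attr: (
        None
        if any(getattr(g, attr) is None for g in gcs)
        else np.mean([getattr(g, attr) for g in gcs], axis=0)
    )
    return GCMatrices(
        igc=mean("igc"), dgc=mean("dgc"), full=mean("full"), pc=mean("pc"),
        estimator_tag=gcs[0].estimator_tag, region_names=gcs[0].region_names,
    )


def bold_baseline_features(scan: RegionalScan) -> np.ndarray:
    """Per-region mean then per-region SD of the raw series (2R features)."""
    return np.concatenate([scan.data.mean(axis=0), scan.data.std(axis=0)])


def build_feature_table(
    scans,
    which: str = "dgc",
    order: int | str = "aic",
    p_max: int = 8,
    average_runs_by_subject: bool = False,
    transform=None,
) -> FeatureTable:
    """Estimate connectivity per scan and assemble a labelled feature table.

    ``order="aic"`` selects the model order per scan. ``transform`` is an
    optional callable applied to each scan before estimation (e.g. ZCA
    whitening returning ``(scan, tf)`` or a plain scan). With
    ``average_runs_by_subject``, per-run estimates are averaged within each
    (subject, condition) before vectorization, one row per subject-condition.
    """
    from .gc_core import gc_matrices, select_order_aic

    gcs, labels, subjects = [], [], []
    for scan in scans:
        if transform is not None:
            out = transform(scan)
            scan = out[0] if isinstance(out, tuple) else out
        p = select_order_aic(scan, p_max) if order == "aic" else int(order)
        gcs.append(gc_matrices(scan, p))
        labels.append(scan.condition)
        subjects.append(scan.subject_id)
    r = gcs[0].n_regions
    names = gcs[0].region_names
    if average_runs_by_subject:
        groups: dict = {}
        for g, lbl, sub in zip(gcs, labels, subjects):
            groups.setdefault((sub, lbl), []).append(g)
        rows, out_labels, out_subjects = [], [], []
        for (sub, lbl), gs in sorted(groups.items()):
            g = gs[0] if len(gs) == 1 else average_runs(*gs)
            rows.append(vectorize(g, which))
            out_labels.append(lbl)
            out_subjects.append(sub)
    else:
        rows = [vectorize(g, which) for g in gcs]
        out_labels, out_subjects = labels, subjects
    return FeatureTable(
        x=np.array(rows), labels=np.array(out_labels),
        feature_ids=feature_ids(r, which, names),
        subjects=np.array(out_subjects),
        provenance={"measure": which, "order": order},
    )


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(learner: str = "svm", penalty: str = "l2", c: float = 1.0) -> Pipeline:
    """Standardizing linear classifier (z-scoring fitted on training folds only)."""
    if learner == "svm":
        dual = penalty == "l2"
        est = LinearSVC(C=c, penalty=penalty, dual=dual, max_iter=20000)
    elif learner == "logistic":
        est = LogisticRegression(
            C=c, l1_ratio=1.0 if penalty == "l1" else 0.0,
            solver="liblinear" if penalty == "l1" else "lbfgs", max_iter=5000,
        )
    else:
        raise ValueError(f"unknown learner {learner!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


_HYPER_GRID = {
    "clf__C": np.logspace(-4, 4, 5).tolist(),
}


def _cv_splitter(scheme: str, y, seed):
    if scheme == "loo":
        return LeaveOneOut()
    if scheme == "kfold10":
        n_splits = min(10, int(np.min(np.bincount(pd.factorize(y)[0]))))
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    raise ValueError(f"unknown CV scheme {scheme!r}")


def _binary_metrics(y_true, y_pred, positive):
    tp = np.sum((y_pred == positive) & (y_true == positive))
    fp = np.sum((y_pred == positive) & (y_true != positive))
    fn = np.sum((y_pred != positive) & (y_true == positive))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return float(precision), float(recall)


def two_way_classify(
    table: FeatureTable,
    scheme: str = "loo",
    hyperopt: bool = False,
    estimator: Pipeline | None = None,
    seed: int = 0,
) -> CVResult:
    """Binary condition decoding with a linear classifier.

    Without hyperparameter search, a default linear SVM is cross-validated
    (leave-one-out or stratified 10-fold). With ``hyperopt``, the cohort is
    split into five folds; each fold in turn serves as the tuning set (an
    internal grid search over the regularization strength, penalty, and
    learner), and accuracy is measured on the held-out remainder; reported
    accuracy pools the held-out predictions over the five tuning folds.
    """
    y = table.labels
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"two-way classification needs two classes, got {len(classes)}")
    est = estimator if estimator is not None else make_classifier()
    if hyperopt:
        correct, total = 0, 0
        preds = np.empty(len(y), dtype=object)
        outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        folds = []
        for test_rest, tune in outer.split(table.x, y):
            search_space = []
            for learner in ("svm", "logistic"):
                for penalty in ("l2", "l1"):
                    for c in _HYPER_GRID["clf__C"]:
                        search_space.append((learner, penalty, c))
            best, best_acc = None, -1.0
            inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + 1)
            for learner, penalty, c in search_space:
                cand = make_classifier(learner, penalty, c)
                accs = []
                for tr, te in inner.split(table.x[tune], y[tune]):
                    cand.fit(table.x[tune][tr], y[tune][tr])
                    accs.append(np.mean(cand.predict(table.x[tune][te]) == y[tune][te]))
                if np.mean(accs) > best_acc:
                    best, best_acc = (learner, penalty, c), float(np.mean(accs))
            model = make_classifier(*best).fit(table.x[tune], y[tune])
            p = model.predict(table.x[test_rest])
            preds[test_rest] = p
            correct += int(np.sum(p == y[test_rest]))
            total += len(test_rest)
            folds.append({"chosen": best, "holdout_accuracy": float(np.mean(p == y[test_rest]))})
        # each sample is predicted once per tuning fold in which it is held out
        acc = correct / total
        k, n = correct, total
        y_eval, y_pred = y, preds.astype(str)
        scheme_tag = "hyperopt5"
    else:
        cv = _cv_splitter(scheme, y, seed)
        y_pred = cross_val_predict(est, table.x, y, cv=cv)
        acc = float(np.mean(y_pred == y))
        k, n = int(np.sum(y_pred == y)), len(y)
        y_eval = y
        folds = []
        scheme_tag = scheme
    lo, hi = clopper_pearson(k, n)
    prec, rec = _binary_metrics(np.asarray(y_eval), np.asarray(y_pred), classes[-1])
    return CVResult(
        accuracy=acc, ci_low=lo, ci_high=hi, precision=prec, recall=rec,
        per_fold=folds, scheme=scheme_tag, n=n,
        provenance={"seed": seed, "classes": classes.tolist()},
    )


def nway_classify(table: FeatureTable, seed: int = 0, scheme: str = "loo") -> CVResult:
    """One-versus-all multiclass decoding (N binary learners, argmax margin)."""
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two members")
    if len(classes) == 2:
        return two_way_classify(table, scheme=scheme, seed=seed)
    est = Pipeline([
        ("scale", StandardScaler()),
        ("clf", OneVsRestClassifier(LinearSVC(C=1.0, max_iter=20000))),
    ])
    cv = _cv_splitter(scheme, y, seed)
    y_pred = cross_val_predict(est, table.x, y, cv=cv)
    acc = float(np.mean(y_pred == y))
    k, n = int(np.sum(y_pred == y)), len(y)
    lo, hi = clopper_pearson(k, n)
    return CVResult(
        accuracy=acc, ci_low=lo, ci_high=hi, precision=float("nan"),
        recall=float("nan"), per_fold=[], scheme=scheme, n=n,
        provenance={"seed": seed, "classes": classes.tolist()},
    )


def _kfold_accuracy(x, y, seed, estimator=None):
    est = estimator if estimator is not None else make_classifier()
    cv = _cv_splitter("kfold10", y, seed)
    y_pred = cross_val_predict(est, x, y, cv=cv)
    return float(np.mean(y_pred == y))


def permutation_test(
    table: FeatureTable,
    n_perm: int = 1000,
    seed: int = 0,
    estimator: Pipeline | None = None,
) -> float:
    """Permutation p value of the 10-fold cross-validation accuracy.

    Labels are permuted within each subject's own scans when subject
    identifiers are present (each subject's condition labels are shuffled
    independently), otherwise globally. p = (b + 1) / (n_perm + 1) where b
    counts null accuracies >= the observed one.
    """
    rng = np.random.default_rng(seed)
    observed = _kfold_accuracy(table.x, table.labels, seed, estimator)
    b = 0
    y = np.asarray(table.labels)
    for i in range(n_perm):
        if table.subjects is not None:
            perm = y.copy()
            for s in np.unique(table.subjects):
                idx = np.flatnonzero(table.subjects == s)
                perm[idx] = perm[rng.permutation(idx)]
        else:
            perm = y[rng.permutation(len(y))]
        if _kfold_accuracy(table.x, perm, seed, estimator) >= observed:
            b += 1
    return (b + 1) / (n_perm + 1)


def subject_average_classify(
    table: FeatureTable,
    m_values=(2, 4, 5, 10, 25, 50),
    seed: int = 0,
) -> dict[int, float]:
    """Accuracy of classifying feature vectors averaged over m held-out subjects.

    Subjects are split in half; a classifier trained on one half predicts the
    class of held-out features averaged within folds of m same-class subjects,
    and the halves are then exchanged. Averaging removes uncorrelated
    estimation noise, so accuracy typically grows with m.
    """
    if table.subjects is None:
        raise ValueError("subject identifiers are required")
    rng = np.random.default_rng(seed)
    subjects = np.unique(table.subjects)
    half = len(subjects) // 2
    perm = rng.permutation(subjects)
    halves = (perm[:half], perm[half : 2 * half])
    out: dict[int, float] = {}
    for m in m_values:
        if m > half:
            raise ValueError(f"m={m} exceeds the half-cohort size {half}")
        correct, total = 0, 0
        for train_subj, test_subj in (halves, halves[::-1]):
            tr = np.isin(table.subjects, train_subj)
            model = make_classifier().fit(table.x[tr], table.labels[tr])
            for cls in np.unique(table.labels):
                te = np.flatnonzero(
                    np.isin(table.subjects, test_subj) & (table.labels == cls)
                )
                rng.shuffle(te)
                for start in range(0, len(te) - m + 1, m):
                    fold = te[start : start + m]
                    pred = model.predict(table.x[fold].mean(axis=0, keepdims=True))[0]
                    correct += int(pred == cls)
                    total += 1
        out[int(m)] = correct / total if total else float("nan")
    return out
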
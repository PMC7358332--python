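"""Predicting per-individual behavioral scores from connectivity features.

Each score is predicted out-of-sample with leave-one-out ridge regression on
the connectivity feature vectors; prediction quality is assessed with
Wilcox's percentage-bend correlation (robust to marginal outliers) and
significance across the score battery is controlled with the
Benjamini-Yekutieli false-discovery procedure, which is valid under arbitrary
dependence between scores. A composite (all scores z-scored and stacked)
tests whether connectivity identifies individuals: the correlation between a
subject's predicted and own observed composite should exceed the
between-subject correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import Ridge
from sklearn.svm import LinearSVR
from statsmodels.stats.multitest import multipletests

from .classification import FeatureTable

__all__ = [
    "ScoreTable",
    "PredictionResult",
    "loo_predict",
    "percentage_bend_corr",
    "by_correct",
    "composite_identify",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """subjects x scores values with an explicit missing mask (NaN = missing)."""

    values: np.ndarray
    score_names: list[str]
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.score_names):
            raise ValueError("score_names must match the column count")
        for k, name in enumerate(self.score_names):
            col = self.values[:, k]
            col = col[~np.isnan(col)]
            if len(np.unique(col)) < 2 and len(col):
                raise ValueError(f"score {name!r} has fewer than two distinct values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        return cls(values=df.to_numpy(float), score_names=[str(c) for c in df.columns],
                   subjects=np.asarray(df.index))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class PredictionResult:
    """Per-score out-of-sample predictions and robust-correlation statistics."""

    per_score: dict[str, dict] = field(default_factory=dict)
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(score=name, r=d["r"], p=d["p"], significant=d["significant"],
                 n=len(d["observed"]))
            for name, d in self.per_score.items()
        ]
        return pd.DataFrame(rows)


def _loo_ridge_predictions(x: np.ndarray, y: np.ndarray, alpha_reg: float,
                           epsilon_insensitive: bool) -> np.ndarray:
    """Out-of-sample predictions: one regressor fit per left-out subject.

    Features are z-scored with training-fold statistics only; the held-out
    subject's score never enters its own fit.
    """
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        xt = (x[tr] - mu) / sd
        if epsilon_insensitive:
            model = LinearSVR(C=1.0 / alpha_reg, epsilon=0.0, max_iter=20000)
        else:
            model = Ridge(alpha=alpha_reg)
        model.fit(xt, y[tr])
        preds[i] = model.predict(((x[i] - mu) / sd)[None, :])[0]
    return preds


def loo_predict(
    features: FeatureTable,
    scores: ScoreTable,
    alpha_reg: float = 1.0,
    alpha: float = 0.05,
    bend: float = 0.2,
    epsilon_insensitive: bool = False,
    min_subjects: int = 10,
    alternative: str = "greater",
) -> PredictionResult:
    """Leave-one-out linear prediction of every score from the features.

    Per score, subjects with a missing value are dropped; with fewer than
    ``min_subjects`` complete subjects the score is skipped (logged). The
    default regressor is ridge regression; ``epsilon_insensitive`` switches to
    a linear support-vector regressor. Predicted and observed scores are
    compared with the percentage-bend correlation, and the per-score p values
    are flagged with the Benjamini-Yekutieli correction at level ``alpha``.

    By default significance is one-sided for positive association
    (``alternative="greater"``): out-of-sample predictions are systematically
    anti-correlated with the held-out scores under the null (the left-out
    subject never informs its own fit, so predictions shrink toward the other
    subjects' mean), and at small n a two-sided test flags those negative
    artifacts as discoveries. Pass ``alternative="two-sided"`` for the raw
    two-sided test.
    """
    if features.x.shape[0] != scores.n_subjects:
        raise ValueError("feature rows and score rows must align (one per subject)")
    result = PredictionResult(alpha=alpha)
    pvals, names = [], []
    for k, name in enumerate(scores.score_names):
        col = scores.values[:, k]
        mask = ~np.isnan(col)
        if mask.sum() < min_subjects:
            logger.warning("score %s skipped: only %d complete subjects",
                           name, int(mask.sum()))
            continue
        preds = _loo_ridge_predictions(features.x[mask], col[mask], alpha_reg,
                                       epsilon_insensitive)
        r, p = percentage_bend_corr(preds, col[mask], bend=bend)
        if alternative == "greater":
            p = p / 2 if r > 0 else 1 - p / 2
        elif alternative != "two-sided":
            raise ValueError(f"unknown alternative {alternative!r}")
        result.per_score[name] = {
            "observed": col[mask], "predicted": preds, "r": r, "p": p,
            "mask": mask,
        }
        pvals.append(p)
        names.append(name)
    flags = by_correct(np.array(pvals), alpha=alpha) if pvals else np.array([], bool)
    for name, flag in zip(names, flags):
        result.per_score[name]["significant"] = bool(flag)
    return result


def percentage_bend_corr(x: np.ndarray, y: np.ndarray, bend: float = 0.2):
    """Wilcox's percentage-bend correlation and its t-approximation p value.

    Marginal observations beyond the (1 - bend) quantile of absolute
    deviations from the median are winsorized through the bend function
    psi(u) = max(-1, min(1, u)), making r insensitive to a bounded fraction
    of outliers in either margin. bend -> 0 recovers Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("x and y must be equal-length vectors with n >= 4")
    n = len(x)

    def psi_scores(v):
        med = np.median(v)
        w = np.sort(np.abs(v - med))
        m = int(np.floor((1.0 - bend) * n + 0.5))
        omega = w[m - 1]
        if omega <= 0:
            raise ValueError("zero robust scale; data nearly constant")
        z = (v - med) / omega
        i1 = int(np.sum(z < -1))
        i2 = int(np.sum(z > 1))
        sel = v[(z >= -1) & (z <= 1)]
        phi = (omega * (i2 - i1) + sel.sum()) / (n - i1 - i2)
        u = (v - phi) / omega
        return np.clip(u, -1.0, 1.0)

    a = psi_scores(x)
    b = psi_scores(y)
    r = float(a @ b / np.sqrt((a @ a) * (b @ b)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * scipy.stats.t.sf(abs(t), n - 2)
    return r, float(p)


def by_correct(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up significance flags (harmonic-sum factor)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_by")[0]


def composite_identify(
    features: FeatureTable,
    scores: ScoreTable,
    alpha_reg: float = 1.0,
):
    """Subject identification from predicted composite behavioral scores.

    Complete-case subjects only. Each score column is z-scored across
    subjects; every score is predicted out-of-sample with the leave-one-out
    regressor; then each subject's predicted composite vector is correlated
    with every subject's observed composite vector. Returns the subjects x
    subjects correlation matrix and the two-sample Kolmogorov-Smirnov test of
    diagonal (self) versus off-diagonal (other) correlations, one-sided for
    the diagonal being stochastically larger.
    """
    complete = ~np.isnan(scores.values).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need at least two complete-case subjects")
    vals = scores.values[complete]
    x = features.x[complete]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    n, k = z.shape
    predicted = np.column_stack(
        [_loo_ridge_predictions(x, z[:, j], alpha_reg, False) for j in range(k)]
    )
    corr = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            corr[i, j] = np.corrcoef(predicted[i], z[j])[0, 1]
    diag = np.diag(corr)
    off = corr[~np.eye(n, dtype=bool)]
    # alternative="less": the diagonal sample's CDF lies below, i.e. the
    # self-correlations are stochastically larger
    ks = scipy.stats.ks_2samp(diag, off, alternative="less")
    return corr, float(ks.statistic), float(ks.pvalue)
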
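"""Conditional Granger-Geweke connectivity from multivariate autoregressions.

The scan's regions are modelled jointly as a vector autoregression (VAR) of
order p. For every unordered region pair (x, y), with z the remaining
regions, the total conditional linear dependence decomposes additively as

    F_{x,y|z} = F_{x->y|z} + F_{y->x|z} + F_{x o y|z}

where the directed terms are log ratios of reduced-model (source's past
omitted) to full-model innovation variances of the target, and the
instantaneous term measures the same-sample dependence of the full model's
innovations. Partial correlation, the zero-lag counterpart, is derived from
the precision matrix.

All regressions are segment-aware: lagged (predictor, response) pairs are
pooled within the contiguous segments of a :class:`~slowgc.io_qc.RegionalScan`
and never span a segment junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_qc import RegionalScan

__all__ = [
    "VARModel",
    "GCMatrices",
    "LaggedCov",
    "fit_var",
    "select_order_aic",
    "conditional_gc_pair",
    "gc_matrices",
    "one_stage_gc",
    "partial_correlation",
    "lagged_covariance",
    "stationary_cov_var",
    "var_autocovariances",
    "population_gc_matrices",
    "companion_spectral_radius",
    "var_residuals",
]

_SYM_TOL = 1e-10


@dataclass
class VARModel:
    """Order-p vector autoregression: x_t = sum_k A_k x_{t-k} + e_t, e ~ N(0, S)."""

    order: int
    coeffs: list[np.ndarray]  # p matrices, each (R, R)
    resid_cov: np.ndarray  # (R, R)
    n_obs: int  # effective regression sample count
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeffs = [np.asarray(a, float) for a in self.coeffs]
        self.resid_cov = np.asarray(self.resid_cov, float)
        if self.order < 1 or len(self.coeffs) != self.order:
            raise ValueError("order must be >= 1 with one coefficient matrix per lag")
        if np.max(np.abs(self.resid_cov - self.resid_cov.T)) > _SYM_TOL:
            raise ValueError("residual covariance must be symmetric")
        self.resid_cov = 0.5 * (self.resid_cov + self.resid_cov.T)

    @property
    def n_regions(self) -> int:
        return self.resid_cov.shape[0]

    def companion(self) -> np.ndarray:
        r, p = self.n_regions, self.order
        c = np.zeros((r * p, r * p))
        c[:r] = np.hstack(self.coeffs)
        if p > 1:
            c[r:, :-r] = np.eye(r * (p - 1))
        return c

    def is_stable(self) -> bool:
        return companion_spectral_radius(self) < 1.0


@dataclass
class GCMatrices:
    """Per-scan connectivity matrices.

    ``dgc[i, j]`` is the directed influence from source region j to
    destination region i (source at column, destination at row). ``igc`` and
    ``pc`` are symmetric with zero (igc) or unit (pc) diagonal; ``full``
    houses the total conditional linear dependence of each pair.
    """

    igc: np.ndarray
    dgc: np.ndarray
    full: np.ndarray
    pc: np.ndarray | None = None
    estimator_tag: str = "two-stage"
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("igc", "full"):
            m = getattr(self, name)
            if m is not None and np.max(np.abs(m - m.T)) > 1e-8:
                raise ValueError(f"{name} matrix must be symmetric")
        if self.pc is not None and np.max(np.abs(self.pc)) > 1.0 + 1e-8:
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.igc.shape[0]

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator_tag,
            "region_names": self.region_names,
            "igc": self.igc.tolist(),
            "dgc": self.dgc.tolist(),
            "full": self.full.tolist(),
            "pc": None if self.pc is None else self.pc.tolist(),
        }

    def to_edge_list(self):
        """Flat (source, destination, measure, value) table.

        Directed entries appear once per ordered pair; symmetric measures once
        per unordered pair.
        """
        import pandas as pd

        r = self.n_regions
        names = self.region_names or [str(k) for k in range(r)]
        rows = []
        for i in range(r):
            for j in range(r):
                if i == j:
                    continue
                rows.append((names[j], names[i], "dgc", self.dgc[i, j]))
                if j > i:
                    rows.append((names[i], names[j], "igc", self.igc[i, j]))
                    rows.append((names[i], names[j], "full", self.full[i, j]))
                    if self.pc is not None:
                        rows.append((names[i], names[j], "pc", self.pc[i, j]))
        return pd.DataFrame(rows, columns=["source", "destination", "measure", "value"])


@dataclass
class LaggedCov:
    lag: int
    matrix: np.ndarray


# ---------------------------------------------------------------------------
# segment-aware regression plumbing


def _demeaned_segments(scan: RegionalScan) -> list[np.ndarray]:
    return [seg - seg.mean(axis=0) for seg in scan.segment_arrays()]


def _pooled_design(scan: RegionalScan, order: int, columns=None, skip: int | None = None):
    """Stack (lagged predictors, responses) over segments, never across junctions.

    ``skip`` rows (>= order) are dropped at the start of each segment, so that
    fits of different orders can share an identical response sample.
    """
    skip = order if skip is None else skip
    if skip < order:
        raise ValueError("skip must be >= order")
    xs, ys = [], []
    for seg in _demeaned_segments(scan):
        if columns is not None:
            seg = seg[:, columns]
        if len(seg) <= skip:
            raise ValueError(
                f"segment of length {len(seg)} too short for VAR order {order}"
            )
        y = seg[skip:]
        x = np.hstack([seg[skip - k : len(seg) - k] for k in range(1, order + 1)])
        xs.append(x)
        ys.append(y)
    return np.vstack(xs), np.vstack(ys)


def _ols(x: np.ndarray, y: np.ndarray, label_cols=None):
    b, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        _, _, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        names = [label_cols[c] for c in bad] if label_cols else bad
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix; dependent columns: {names}"
        )
    resid = y - x @ b
    cov = resid.T @ resid / len(y)
    return b, 0.5 * (cov + cov.T), resid


def fit_var(scan: RegionalScan, order: int) -> VARModel:
    """Ordinary-least-squares VAR(p) fit pooling lagged pairs from all segments.

    Columns are demeaned per segment before fitting; the residual covariance
    is normalized by the effective (pooled) sample count.
    """
    x, y = _pooled_design(scan, order)
    r = scan.n_regions
    labels = [
        f"{(scan.region_names or list(range(r)))[c % r]}@lag{c // r + 1}"
        for c in range(order * r)
    ]
    b, cov, _ = _ols(x, y, labels)
    coeffs = [b[k * r : (k + 1) * r].T for k in range(order)]
    return VARModel(order=order, coeffs=coeffs, resid_cov=cov, n_obs=len(y),
                    region_names=scan.region_names)


def var_residuals(scan: RegionalScan, model: VARModel) -> np.ndarray:
    """Residuals of ``model`` applied to ``scan`` (pooled over segments)."""
    x, y = _pooled_design(scan, model.order)
    b = np.vstack([a.T for a in model.coeffs])
    return y - x @ b


def select_order_aic(scan: RegionalScan, p_max: int) -> int:
    """Smallest-AIC model order over p in [1, p_max] (ties -> smallest p).

    All candidate orders are fitted on an identical response sample (the first
    ``p_max`` rows of each segment are excluded for every candidate).
    """
    r = scan.n_regions
    best_p, best_aic = 1, math.inf
    for p in range(1, p_max + 1):
        x, y = _pooled_design(scan, p, skip=p_max)
        _, cov, _ = _ols(x, y)
        n = len(y)
        aic = _logdet(cov) + 2.0 * p * r * r / n
        if aic < best_aic - 1e-12:
            best_p, best_aic = p, aic
    return best_p


def _logdet(m: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(m)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite")
    return val


def companion_spectral_radius(model: VARModel) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(model.companion()))))


# ---------------------------------------------------------------------------
# Geweke measures, two-stage (separate full and reduced regressions)


def _reduced_variances(scan: RegionalScan, order: int, excluded: int) -> np.ndarray:
    """Innovation variances of every retained region when ``excluded`` is omitted."""
    cols = [c for c in range(scan.n_regions) if c != excluded]
    x, y = _pooled_design(scan, order, columns=cols)
    _, cov, _ = _ols(x, y)
    out = np.full(scan.n_regions, np.nan)
    out[cols] = np.diag(cov)
    return out


def _pair_terms(var_full: np.ndarray, cov_full: np.ndarray,
                red: dict[int, np.ndarray], i: int, j: int):
    """The four Geweke terms for pair (i, j) given full + reduced variances."""
    block = cov_full[np.ix_([i, j], [i, j])]
    det_block = block[0, 0] * block[1, 1] - block[0, 1] * block[1, 0]
    if det_block <= 0 or var_full[i] <= 0 or var_full[j] <= 0:
        raise FloatingPointError("nonpositive innovation variance: degenerate fit")
    f_i_to_j = math.log(red[i][j] / var_full[j])  # omit i, predict j
    f_j_to_i = math.log(red[j][i] / var_full[i])
    f_inst = math.log(var_full[i] * var_full[j] / det_block)
    f_full = math.log(red[j][i] * red[i][j] / det_block)
    return f_i_to_j, f_j_to_i, f_inst, f_full


def conditional_gc_pair(scan: RegionalScan, i: int, j: int, order: int):
    """Two-stage conditional GC terms for regions (i, j) given all others.

    Returns ``(F_{i->j|z}, F_{j->i|z}, F_{i o j|z}, F_{i,j|z})``. The full
    measure equals the sum of the other three by construction.
    """
    if i == j:
        raise ValueError("need two distinct regions")
    full = fit_var(scan, order)
    red = {k: _reduced_variances(scan, order, k) for k in (i, j)}
    return _pair_terms(np.diag(full.resid_cov), full.resid_cov, red, i, j)


def gc_matrices(scan: RegionalScan, order: int, with_pc: bool = True) -> GCMatrices:
    """All-pairs conditional GC matrices via the two-stage estimator.

    One full regression plus one reduced regression per omitted region
    (shared across all pairs involving that region).
    """
    r = scan.n_regions
    full = fit_var(scan, order)
    var_full = np.diag(full.resid_cov)
    red = {k: _reduced_variances(scan, order, k) for k in range(r)}
    return _assemble(
        var_full, full.resid_cov, red, r,
        pc=partial_correlation(scan) if with_pc else None,
        tag="two-stage", names=scan.region_names,
    )


def _assemble(var_full, cov_full, red, r, pc, tag, names) -> GCMatrices:
    igc = np.zeros((r, r))
    dgc = np.zeros((r, r))
    fullm = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            fij, fji, finst, ftot = _pair_terms(var_full, cov_full, red, i, j)
            igc[i, j] = igc[j, i] = finst
            fullm[i, j] = fullm[j, i] = ftot
            dgc[j, i] = fij  # source i at column, destination j at row
            dgc[i, j] = fji
    return GCMatrices(igc=igc, dgc=dgc, full=fullm, pc=pc,
                      estimator_tag=tag, region_names=names)


# ---------------------------------------------------------------------------
# population quantities and the one-stage estimator


def stationary_cov_var(model: VARModel) -> np.ndarray:
    """Zero-lag stationary covariance G(0) of a stable VAR (companion Lyapunov)."""
    if not model.is_stable():
        raise ValueError("VAR model is unstable; no stationary covariance exists")
    r, p = model.n_regions, model.order
    sig_c = np.zeros((r * p, r * p))
    sig_c[:r, :r] = model.resid_cov
    gamma_c = scipy.linalg.solve_discrete_lyapunov(model.companion(), sig_c)
    g0 = gamma_c[:r, :r]
    return 0.5 * (g0 + g0.T)


def var_autocovariances(model: VARModel, max_lag: int) -> list[np.ndarray]:
    """[G(0), ..., G(max_lag)] with G(k) = E[x_t x_{t-k}^T], from the model."""
    r, p = model.n_regions, model.order
    gamma_c = None
    if p > 1:
        sig_c = np.zeros((r * p, r * p))
        sig_c[:r, :r] = model.resid_cov
        if not model.is_stable():
            raise ValueError("VAR model is unstable")
        gamma_c = scipy.linalg.solve_discrete_lyapunov(model.companion(), sig_c)
        gammas = [gamma_c[:r, k * r : (k + 1) * r] for k in range(p)]
    else:
        gammas = [stationary_cov_var(model)]
    gammas[0] = 0.5 * (gammas[0] + gammas[0].T)
    while len(gammas) <= max_lag:
        k = len(gammas)
        g = np.zeros((r, r))
        for m, a in enumerate(model.coeffs, start=1):
            gm = gammas[k - m] if k - m >= 0 else gammas[m - k].T
            g += a @ gm
        gammas.append(g)
    return gammas[: max_lag + 1]


def _reduced_from_gammas(gammas: list[np.ndarray], subset: list[int], order: int):
    """Optimal order-p linear predictor of the subset process from population
    autocovariances (Yule-Walker normal equations restricted to the subset)."""
    s = list(subset)
    m = len(s)

    def g(k):  # G(k) restricted to the subset, k may be negative
        full = gammas[k] if k >= 0 else gammas[-k].T
        return full[np.ix_(s, s)]

    big = np.block([[g(l - k) for l in range(1, order + 1)] for k in range(1, order + 1)])
    c = np.hstack([g(k) for k in range(1, order + 1)])
    b = np.linalg.solve(big, c.T).T  # (m, m*order)
    v = g(0) - b @ c.T
    return b, 0.5 * (v + v.T)


def population_gc_matrices(model: VARModel, order: int | None = None,
                           with_pc: bool = True) -> GCMatrices:
    """Exact (population) conditional GC of a known VAR model.

    Full and reduced regressions are solved analytically from the model's
    autocovariance sequence at the stated order; all GC values are therefore
    nonnegative and free of sampling error.
    """
    order = model.order if order is None else order
    r = model.n_regions
    gammas = var_autocovariances(model, order)
    _, cov_full = _reduced_from_gammas(gammas, list(range(r)), order)
    var_full = np.diag(cov_full)
    red = {}
    for k in range(r):
        cols = [c for c in range(r) if c != k]
        _, v = _reduced_from_gammas(gammas, cols, order)
        out = np.full(r, np.nan)
        out[cols] = np.diag(v)
        red[k] = out
    pc = None
    if with_pc:
        pc = _pc_from_cov(stationary_cov_var(model))
    return _assemble(var_full, cov_full, red, r, pc=pc,
                     tag="population", names=model.region_names)


def one_stage_gc(scan: RegionalScan, order: int, with_pc: bool = True) -> GCMatrices:
    """Conditional GC from a single full regression.

    The reduced models' innovation variances are obtained analytically from
    the fitted full model's implied autocovariance sequence (via the companion
    Lyapunov equation) instead of by refitting on data. The instantaneous
    measure coincides with the two-stage estimator (both come from the full
    model's residual covariance); only the directed and full measures differ.
    """
    full = fit_var(scan, order)
    if not full.is_stable():
        raise ValueError("fitted full model is unstable; one-stage GC undefined")
    r = scan.n_regions
    gammas = var_autocovariances(full, order)
    red = {}
    for k in range(r):
        cols = [c for c in range(r) if c != k]
        _, v = _reduced_from_gammas(gammas, cols, order)
        out = np.full(r, np.nan)
        out[cols] = np.diag(v)
        red[k] = out
    return _assemble(
        np.diag(full.resid_cov), full.resid_cov, red, r,
        pc=partial_correlation(scan) if with_pc else None,
        tag="one-stage", names=scan.region_names,
    )


# ---------------------------------------------------------------------------
# zero-lag measures


def _pc_from_cov(cov: np.ndarray) -> np.ndarray:
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; consider the shrinkage flag"
        ) from exc
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return np.clip(0.5 * (pc + pc.T), -1.0, 1.0)


def partial_correlation(scan: RegionalScan, shrinkage: float | None = None) -> np.ndarray:
    """Partial correlations from the precision matrix of the sample covariance.

    ``PC_ij = -P_ij / sqrt(P_ii P_jj)`` where P is the inverse of the
    (per-segment demeaned) covariance. ``shrinkage`` mixes in a scaled
    identity: ``(1 - a) C + a tr(C)/R I``.
    """
    cov = lagged_covariance(scan, 0).matrix
    if shrinkage:
        r = cov.shape[0]
        cov = (1 - shrinkage) * cov + shrinkage * np.trace(cov) / r * np.eye(r)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "covariance is singular or near-singular; pass shrinkage > 0"
        )
    return _pc_from_cov(cov)


def lagged_covariance(scan: RegionalScan, lag: int) -> LaggedCov:
    """Sample lagged covariance E[x_t x_{t-lag}^T], never pairing across junctions."""
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    acc = np.zeros((scan.n_regions, scan.n_regions))
    n = 0
    for seg in _demeaned_segments(scan):
        if len(seg) <= lag:
            raise ValueError(f"segment of length {len(seg)} shorter than lag {lag}")
        a, b = seg[lag:], seg[: len(seg) - lag]
        acc += a.T @ b
        n += len(a)
    m = acc / n
    if lag == 0:
        m = 0.5 * (m + m.T)
    return LaggedCov(lag=lag, matrix=m)
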
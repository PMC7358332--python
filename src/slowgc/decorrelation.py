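"""Purging regional time series of instantaneous correlations.

Two routes: ZCA (Mahalanobis) whitening of a single scan, which among all
whitening transforms yields output closest to the input in least squares and
so preserves region identity across subjects; and joint decorrelation of a
scan pair via the generalized eigenvectors of their covariance matrices,
which diagonalizes both covariances with a single shared projection.
Connectivity estimated on the projected series isolates the lag-based
component of dependence from the instantaneous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .gc_core import lagged_covariance
from .io_qc import RegionalScan

__all__ = ["WhiteningTransform", "zca_whiten", "gev_decorrelate"]


@dataclass
class WhiteningTransform:
    matrix: np.ndarray
    method: str  # "zca" | "gev"
    diagnostics: dict = field(default_factory=dict)

    def apply(self, scan: RegionalScan) -> RegionalScan:
        return scan.with_data(scan.data @ self.matrix, segments=scan.segments)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "matrix": self.matrix.tolist(),
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


def _scan_cov(scan: RegionalScan, shrinkage: float | None) -> np.ndarray:
    cov = lagged_covariance(scan, 0).matrix
    if shrinkage:
        r = cov.shape[0]
        cov = (1 - shrinkage) * cov + shrinkage * np.trace(cov) / r * np.eye(r)
    return cov


def _check_full_rank(cov: np.ndarray, what: str) -> None:
    if np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            f"{what} covariance is rank-deficient; pass shrinkage > 0"
        )


def zca_whiten(
    scan: RegionalScan, shrinkage: float | None = None
) -> tuple[RegionalScan, WhiteningTransform]:
    """ZCA-whiten a scan: Y = X C^{-1/2} with C the scan covariance.

    The transform E D^{-1/2} E^T (eigendecomposition C = E D E^T) is symmetric
    and equals C^{-1/2}; the output has identity covariance and is the
    whitened dataset closest to the input in least squares.
    """
    cov = _scan_cov(scan, shrinkage)
    _check_full_rank(cov, "scan")
    d, e = np.linalg.eigh(cov)
    w = e @ np.diag(1.0 / np.sqrt(d)) @ e.T
    tf = WhiteningTransform(matrix=w, method="zca", diagnostics={"D": d, "E": e})
    return tf.apply(scan), tf


def gev_decorrelate(
    task_scan: RegionalScan,
    rest_scan: RegionalScan,
    shrinkage: float | None = None,
    literal_construction: bool = False,
) -> tuple[RegionalScan, RegionalScan, WhiteningTransform]:
    """Jointly decorrelate two scans with one shared projection.

    The projection G simultaneously diagonalizes both covariance matrices
    (G^T C_T G and G^T C_R G diagonal), obtained from the symmetric-definite
    generalized eigenproblem C_R g = lambda C_T g (equivalently: whiten by
    C_T, then eigendecompose the whitened C_R). ``literal_construction``
    instead forms E_T D_T^{-1/2} E_R from the two separate eigendecompositions
    for comparison; that product does not jointly diagonalize in general.
    """
    if task_scan.n_regions != rest_scan.n_regions:
        raise ValueError("scans must share the region count")
    c_t = _scan_cov(task_scan, shrinkage)
    c_r = _scan_cov(rest_scan, shrinkage)
    _check_full_rank(c_t, "task")
    _check_full_rank(c_r, "rest")
    d_t, e_t = np.linalg.eigh(c_t)
    d_r, e_r = np.linalg.eigh(c_r)
    if literal_construction:
        g = e_t @ np.diag(1.0 / np.sqrt(d_t)) @ e_r
        gen_vals = None
    else:
        gen_vals, g = scipy.linalg.eigh(c_r, c_t)  # G^T C_T G = I
    tf = WhiteningTransform(
        matrix=g, method="gev",
        diagnostics={
            "D_T": d_t, "E_T": e_t, "D_R": d_r, "E_R": e_r,
            "generalized_eigenvalues": gen_vals,
            "literal_construction": literal_construction,
        },
    )
    return tf.apply(task_scan), tf.apply(rest_scan), tf
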
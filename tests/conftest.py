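import numpy as np
import pytest

from slowgc import RegionalScan, VARModel, simulate_var


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def white_scan(rng):
    """500 timepoints of i.i.d. unit-variance noise over 3 regions."""
    return RegionalScan(data=rng.standard_normal((500, 3)), tr=1.0)


@pytest.fixture
def var1_model():
    """Stable bivariate VAR(1): region 0 drives region 1."""
    a = np.array([[0.5, 0.0], [0.5, 0.5]])
    return VARModel(order=1, coeffs=[a], resid_cov=np.eye(2), n_obs=0)


@pytest.fixture
def var1_scan(var1_model):
    return RegionalScan(data=simulate_var(var1_model, 2000, seed=1), tr=1.0)


def naive_conditional_gc(data: np.ndarray, i: int, j: int, order: int):
    """Independent oracle: conditional GC via explicit full/reduced OLS loops.

    Deliberately written as plain nested loops over lagged pairs on a single
    contiguous segment, sharing no code with the library implementation.
    """
    x = data - data.mean(axis=0)
    t, r = x.shape
    p = order

    def ols_resid_cov(cols):
        cols = list(cols)
        rows_y, rows_x = [], []
        for s in range(p, t):
            rows_y.append([x[s, c] for c in cols])
            pred = []
            for k in range(1, p + 1):
                pred.extend(x[s - k, c] for c in cols)
            rows_x.append(pred)
        ym = np.array(rows_y)
        xm = np.array(rows_x)
        beta = np.linalg.lstsq(xm, ym, rcond=None)[0]
        e = ym - xm @ beta
        return (e.T @ e) / len(ym), cols

    cov_full, cols_full = ols_resid_cov(range(r))
    vf = {c: cov_full[k, k] for k, c in enumerate(cols_full)}
    cov_red_i, cols_i = ols_resid_cov([c for c in range(r) if c != j])
    vred_i = cov_red_i[cols_i.index(i), cols_i.index(i)]
    cov_red_j, cols_j = ols_resid_cov([c for c in range(r) if c != i])
    vred_j = cov_red_j[cols_j.index(j), cols_j.index(j)]
    ii, jj = cols_full.index(i), cols_full.index(j)
    det_block = cov_full[ii, ii] * cov_full[jj, jj] - cov_full[ii, jj] ** 2
    f_i_to_j = np.log(vred_j / vf[j])
    f_j_to_i = np.log(vred_i / vf[i])
    f_inst = np.log(vf[i] * vf[j] / det_block)
    f_full = np.log(vred_i * vred_j / det_block)
    return f_i_to_j, f_j_to_i, f_inst, f_full
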
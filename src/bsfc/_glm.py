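"""Vectorized ordinary-least-squares helpers shared by the GLM-based modules.

All group and per-run models in this package are plain OLS fits of many
response columns on one small design matrix, so the solver is written once:
``Y`` is n x m (m responses fitted simultaneously), ``X`` is n x k.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise :class:`DesignError` naming the collinear columns if X is rank-deficient."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    names = names or [f"col{i}" for i in range(X.shape[1])]
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            bad.append(names[j])
    raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols_fit(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X.

    Returns ``(beta, se, df)`` where ``beta`` and ``se`` are k x m and
    ``df = n - k``.  Standard errors use the unbiased residual variance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    df = n - k
    if df < 1:
        raise DesignError(f"insufficient data: n={n} observations for k={k} regressors")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    # a residual variance at rounding level is an exact fit: force se (and
    # hence t) to 0 instead of dividing rounding noise by rounding noise
    scale = np.einsum("ij,ij->j", Y, Y) / max(Y.shape[0], 1)
    sigma2 = np.where(sigma2 <= 1e-24 * (scale + 1.0), 0.0, sigma2)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return beta, se, df


def ols_contrast_t(X: np.ndarray, Y: np.ndarray, coef_index: int):
    """t statistics and two-tailed p-values for one coefficient, per Y column."""
    beta, se, df = ols_fit(X, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[coef_index] > 0, beta[coef_index] / se[coef_index], 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta[coef_index], t, p, df


def residualize(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of Y after projecting out the span of X."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def subject_dummies(subjects: list[str]) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for each subject except the first (reference) level."""
    levels = sorted(dict.fromkeys(subjects))
    cols = [np.asarray([s == lv for s in subjects], dtype=float) for lv in levels[1:]]
    names = [f"subject[{lv}]" for lv in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(subjects), 0)), names
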
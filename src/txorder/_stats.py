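"""Small statistical helpers shared across modules.

Pearson correlation p-values use the exact t-transform
``t = c * sqrt((n - 2) / (1 - c**2))`` referred to Student's t with n - 2
degrees of freedom (two-sided).  Degenerate situations (n < 3, zero
variance, |c| == 1) yield NaN p-values with a flag string instead of raising.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_EPS = 1e-15


def pearson_with_p(x, y) -> tuple[float, int, float, str]:
    """Pearson coefficient, n, two-sided p-value and a degeneracy flag.

    Missing values (NaN) in either vector are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        return np.nan, n, np.nan, "n_too_small"
    sx = x.std()
    sy = y.std()
    if sx < _EPS or sy < _EPS:
        return np.nan, n, np.nan, "zero_variance"
    c = float(np.corrcoef(x, y)[0, 1])
    c = max(-1.0, min(1.0, c))
    if abs(c) >= 1.0 - 1e-13:
        # perfect correlation: coefficient defined, p undefined
        return float(np.sign(c)), n, np.nan, "perfect_correlation"
    t = c * np.sqrt((n - 2) / (1.0 - c * c))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return c, n, float(p), ""


def rowwise_pearson(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Vectorized per-row Pearson of a (rows x conditions) matrix against y.

    NaNs in X are handled per row (pairwise deletion); y must be finite.
    Returns (coefficients, n, p_values, flags); degenerate rows get NaN
    coefficient/p and a non-empty flag.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    M = np.isfinite(X)
    Xf = np.where(M, X, 0.0)
    n = M.sum(axis=1).astype(float)
    sum_x = Xf.sum(axis=1)
    sum_x2 = (Xf * Xf).sum(axis=1)
    sum_y = M @ y
    sum_y2 = M @ (y * y)
    sum_xy = Xf @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sum_xy - sum_x * sum_y
        var_x = n * sum_x2 - sum_x**2
        var_y = n * sum_y2 - sum_y**2
        denom = np.sqrt(var_x * var_y)
        c = cov / denom
    flags = [""] * X.shape[0]
    coeff = np.full(X.shape[0], np.nan)
    pvals = np.full(X.shape[0], np.nan)
    # relative tolerance for zero variance: scale by the magnitude of the data
    scale_x = np.maximum(sum_x2, 1.0)
    scale_y = np.maximum(sum_y2, 1.0)
    for i in range(X.shape[0]):
        ni = int(n[i])
        if ni < 3:
            flags[i] = "n_too_small"
            continue
        if var_x[i] <= 1e-12 * scale_x[i] * ni or var_y[i] <= 1e-12 * scale_y[i] * ni:
            flags[i] = "zero_variance"
            continue
        ci = max(-1.0, min(1.0, float(c[i])))
        if abs(ci) >= 1.0 - 1e-13:
            coeff[i] = np.sign(ci)
            flags[i] = "perfect_correlation"
            continue
        coeff[i] = ci
        t = ci * np.sqrt((ni - 2) / (1.0 - ci * ci))
        pvals[i] = 2.0 * stats.t.sf(abs(t), df=ni - 2)
    return coeff, n.astype(int), pvals, flags


def permutation_pearson_p(
    x: np.ndarray, y: np.ndarray, n_shuffles: int = 100_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the Pearson coefficient.

    Shuffles y against x ``n_shuffles`` times; p is the fraction of shuffles
    (including the observed labelling) with |r| at least the observed |r|.
    Used as an independent cross-check of the t-based p-value.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = abs(float(xc @ yc) / n)
    # vectorized shuffles in blocks to bound memory
    count = 0
    block = 20_000
    done = 0
    while done < n_shuffles:
        b = min(block, n_shuffles - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        r = np.abs((yc[perms] @ xc) / n)
        count += int((r >= r_obs - 1e-12).sum())
        done += b
    return (count + 1) / (n_shuffles + 1)
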
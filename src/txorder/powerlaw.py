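"""Cumulative power-law (Zipf) analysis of gene-expression distributions.

For one condition's expression vector the cumulative probability
``P>(K)`` — the fraction of genes expressed at level at least K — decays
approximately as ``K**(-r)``.  Working with the cumulative curve rather than
the density suppresses the noise that dominates the sparse large-K tail of
the histogram.  The exponent r is estimated by ordinary least squares on the
log-log cumulative curve restricted to a fixed window of log10 expression
(default [-1, 2]).

Ties are handled with the weak inequality (``>=``): the smallest observation
has P> = 1 exactly and no zero probabilities enter the logarithm.  The
regression points are the distinct observed levels inside the window,
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import ConditionTable, ExpressionMatrix, GeneGrowthCorrelation, PowerLawFit
from ._stats import pearson_with_p

DEFAULT_FIT_RANGE = (-1.0, 2.0)


def empirical_cumulative(expression: Sequence[float]) -> np.ndarray:
    """Cumulative curve points (K_log10, P_greater) for one expression vector.

    Input values are log10 expression levels; NaNs are dropped.  Returns an
    (m, 2) array over the m distinct observed levels, sorted ascending in K,
    with P>(K) = #{x >= K} / n so that P> at the minimum level is exactly 1.
    """
    x = np.asarray(expression, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("cumulative curve requires >= 3 non-missing values")
    levels, counts = np.unique(x, return_counts=True)
    if levels.size < 2:
        raise ValueError("degenerate distribution: all values identical")
    n = x.size
    # number of observations >= each distinct level
    ge = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    return np.column_stack([levels, ge / n])


def fit_power_law(
    points: np.ndarray,
    fit_range_log10: tuple[float, float] = DEFAULT_FIT_RANGE,
    condition_id: str = "",
    method: str = "ols",
) -> PowerLawFit:
    """Regression of log10 P>(K) on log10 K inside the fit window.

    ``slope_r`` is minus the regression slope, positive for a decaying
    distribution; at least 3 curve points must fall inside the window.

    The default ``method="ols"`` is the plain unweighted free-intercept
    least-squares fit on the distinct curve points.
    ``method="wls_anchored"`` instead regresses through the window's
    lower-edge curve point with weights ``P / (1 - P)``, the inverse
    (delta-method) sampling variance of the empirical log cumulative
    probability; this brings the slope variance close to the information
    bound ``r / sqrt(n)`` on clean power-law samples but leans heavily on
    the low-K corner, so it is sensitive to measurement noise there.  Both
    methods recover an exact power-law line exactly.
    """
    pts = np.asarray(points, dtype=float)
    lo, hi = fit_range_log10
    if not lo < hi:
        raise ValueError("fit range must be a nonempty interval")
    mask = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
    sel = pts[mask]
    if sel.shape[0] < 3:
        raise ValueError(
            f"only {sel.shape[0]} curve points in fit range [{lo}, {hi}]; need >= 3"
        )
    x = sel[:, 0]
    p = sel[:, 1]
    y = np.log10(p)
    if method == "ols":
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif method == "wls_anchored":
        # anchor at the lowest-K in-window point; its deviation is zero by
        # construction, and near-degenerate weights (P ~ 1) carry no
        # information about the slope
        dx = x - x[0]
        dy = y - y[0]
        w = p / np.maximum(1.0 - p, 1e-12)
        w[0] = 0.0
        w[p >= 1.0 - 1e-12] = 0.0
        denom = (w * dx) @ dx
        if denom <= 0:
            raise ValueError("degenerate curve: no usable points besides the anchor")
        slope = float((w * dx) @ dy / denom)
        intercept = float(y[0] - slope * x[0])
    else:
        raise ValueError(f"unknown fit method {method!r}")
    fitted = intercept + slope * x
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        condition_id=condition_id,
        slope_r=-slope,
        intercept=intercept,
        fit_range_log10=(float(lo), float(hi)),
        r_squared=r2,
        n_points=int(sel.shape[0]),
    )


def fit_condition_slopes(
    condition_matrix: ExpressionMatrix,
    fit_range_log10: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> list[PowerLawFit]:
    """One cumulative power-law fit per condition column."""
    fits = []
    for cid in condition_matrix.dataset_ids:
        curve = empirical_cumulative(condition_matrix.values[cid].to_numpy())
        fits.append(fit_power_law(curve, fit_range_log10, condition_id=cid))
    return fits


@dataclass(frozen=True)
class SlopeGroupComparison:
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_sizes: dict[str, int]
    pairwise_p: dict[tuple[str, str], float]  # Welch two-sample t-test


def compare_slope_groups(
    fits: Sequence[PowerLawFit], grouping: Mapping[str, str]
) -> SlopeGroupComparison:
    """Mean +/- SEM of slope r per group with pairwise Welch t-tests.

    ``grouping`` maps condition_id to a group label (e.g. genome class or
    cellular state).  Every group needs >= 2 members.
    """
    by_group: dict[str, list[float]] = {}
    for f in fits:
        if f.condition_id in grouping:
            by_group.setdefault(grouping[f.condition_id], []).append(f.slope_r)
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups to compare")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    sems = {g: float(stats.sem(v)) for g, v in by_group.items()}
    sizes = {g: len(v) for g, v in by_group.items()}
    labels = sorted(by_group)
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vb = by_group[a], by_group[b]
            if len(va) == len(vb) and np.allclose(va, vb):
                p = 1.0
            else:
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
                if not np.isfinite(p):
                    p = 1.0
            pairwise[(a, b)] = p
    return SlopeGroupComparison(means, sems, sizes, pairwise)


def permutation_slope_test(
    a: Sequence[float],
    b: Sequence[float],
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of group means.

    Exhaustive when the number of label assignments is small, Monte-Carlo
    otherwise; a cross-check for the Welch t-test used by
    :func:`compare_slope_groups`.
    """
    res = stats.permutation_test(
        (np.asarray(a, float), np.asarray(b, float)),
        lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_resamples,
        vectorized=True,
        rng=seed,
    )
    return float(res.pvalue)


def correlate_slopes_with_growth(
    fits: Sequence[PowerLawFit], conditions: ConditionTable
) -> GeneGrowthCorrelation:
    """Pearson correlation of the fitted exponents against growth rate.

    Returns a correlation record with subset label "slopes"; degenerate cases
    (constant slopes, constant growth, n < 3) come back flagged with NaN
    p-value rather than raising.
    """
    rates = conditions.growth_rates()
    pairs = [(f.slope_r, rates[f.condition_id]) for f in fits if f.condition_id in rates.index]
    if len(pairs) < 2:
        raise ValueError("need >= 2 fitted conditions with growth rates")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if len(pairs) == 2:
        # coefficient is +/-1 by construction; p-value undefined
        c = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) >= 0 else -1.0
        return GeneGrowthCorrelation("slope_r", "slopes", c, 2, np.nan, "n_too_small")
    c, n, p, flag = pearson_with_p(x, y)
    return GeneGrowthCorrelation("slope_r", "slopes", c, n, p, flag)
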
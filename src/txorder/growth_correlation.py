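"""Per-gene correlation of expression to growth rate and the improved-gene screen.

Each gene's log10 expression over a chosen subset of conditions is
correlated (Pearson) against the subset's specific growth rates; the
two-sided p-value comes from the exact t-transform with n - 2 degrees of
freedom.  "Improved-correlation" genes are those with no correlation in a
reference subset (p > p_ns) but a highly significant one in a focal subset
(p < p_sig) — the thresholds default to the conventional 0.01 / 0.001 pair.
Each improved gene is classified by whether the coefficient kept (``same``)
or flipped (``reverse``) its sign between the two subsets.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConditionTable,
    ExpressionMatrix,
    GeneGrowthCorrelation,
    ImprovedGene,
)
from ._stats import rowwise_pearson

DEFAULT_P_NS = 0.01
DEFAULT_P_SIG = 0.001


def gene_growth_correlations(
    condition_matrix: ExpressionMatrix,
    conditions: ConditionTable,
    subset_label: str = "all",
    min_conditions: int = 3,
    method: str = "pearson",
) -> list[GeneGrowthCorrelation]:
    """Correlate every gene's expression with growth rate over the given conditions.

    ``conditions`` should already be the desired subset (use
    :meth:`ConditionTable.select`); it must reference columns of
    ``condition_matrix`` and contain at least 3 conditions.  Genes with fewer
    than 3 non-missing values in the subset, or with zero variance, are
    returned flagged (NaN coefficient) rather than dropped, so callers can
    report how many genes were skipped.

    ``method`` is ``"pearson"`` (default) or ``"spearman"`` (Pearson on
    midranks, with the same t-transform p-value).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    cids = [c for c in conditions.condition_ids if c in condition_matrix.values.columns]
    if len(cids) < min_conditions:
        raise ValueError(
            f"subset {subset_label!r} selects {len(cids)} conditions; need >= {min_conditions}"
        )
    sub = condition_matrix.values[cids]
    y = conditions.growth_rates().loc[cids].to_numpy(dtype=float)
    X = sub.to_numpy(dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata

        Xr = np.full_like(X, np.nan)
        for i in range(X.shape[0]):
            m = np.isfinite(X[i])
            if m.sum() >= 2:
                Xr[i, m] = rankdata(X[i, m])
        # y must be ranked within each gene's observed subset; fold the y
        # ranks into the per-row computation by ranking y per missing pattern
        coeff = np.full(X.shape[0], np.nan)
        n_arr = np.zeros(X.shape[0], dtype=int)
        pvals = np.full(X.shape[0], np.nan)
        flags = []
        from ._stats import pearson_with_p

        for i in range(X.shape[0]):
            m = np.isfinite(X[i])
            if m.sum() < 3:
                flags.append("n_too_small")
                n_arr[i] = int(m.sum())
                continue
            c, ni, p, flag = pearson_with_p(Xr[i, m], rankdata(y[m]))
            coeff[i], n_arr[i], pvals[i] = c, ni, p
            flags.append(flag)
        n = n_arr
    else:
        coeff, n, pvals, flags = rowwise_pearson(X, y)
    out = []
    for i, gene in enumerate(sub.index):
        out.append(
            GeneGrowthCorrelation(
                gene_id=str(gene),
                subset_label=subset_label,
                coefficient=float(coeff[i]),
                n=int(n[i]),
                p_value=float(pvals[i]),
                flag=flags[i],
            )
        )
    return out


def correlations_frame(correlations: Sequence[GeneGrowthCorrelation]) -> pd.DataFrame:
    """Tabulate correlation records (index gene_id)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in correlations],
            "subset": [c.subset_label for c in correlations],
            "coefficient": [c.coefficient for c in correlations],
            "n": [c.n for c in correlations],
            "p_value": [c.p_value for c in correlations],
            "flag": [c.flag for c in correlations],
        }
    ).set_index("gene_id")


def correlation_histogram(
    correlations: Sequence[GeneGrowthCorrelation], bin_width: float = 0.1
) -> pd.DataFrame:
    """Counts of genes per coefficient bin over [-1, 1].

    Bins are left-closed right-open except the last, which is closed, so the
    counts sum to the number of non-flagged genes.  ``bin_width`` must divide
    the interval length 2 evenly (20 bins for the default 0.1).
    """
    n_bins = round(2.0 / bin_width)
    if not np.isclose(n_bins * bin_width, 2.0):
        raise ValueError(f"bin_width {bin_width} does not divide [-1, 1] evenly")
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    coeffs = np.array([c.coefficient for c in correlations if c.ok])
    counts, _ = np.histogram(coeffs, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def classify_direction(coeff_A: float, coeff_B: float) -> str:
    """``same`` when the correlation kept its sign, ``reverse`` when it flipped.

    A strengthening negative correlation counts as ``same``.  An exactly zero
    reference coefficient carries no sign of its own and is assigned the
    focal sign, hence ``same``.
    """
    if not (np.isfinite(coeff_A) and np.isfinite(coeff_B)):
        raise ValueError("direction requires both coefficients defined")
    sa, sb = np.sign(coeff_A), np.sign(coeff_B)
    if sa == 0.0:
        sa = sb
    return "same" if sa == sb else "reverse"


def find_improved_genes(
    corr_A: Sequence[GeneGrowthCorrelation],
    corr_B: Sequence[GeneGrowthCorrelation],
    p_ns: float = DEFAULT_P_NS,
    p_sig: float = DEFAULT_P_SIG,
) -> list[ImprovedGene]:
    """Genes non-correlated in the reference subset A but highly correlated in B.

    Selection rule: p_A > p_ns AND p_B < p_sig (strict inequalities at the
    printed thresholds).  Genes flagged degenerate in either subset, or
    present in only one, are excluded.
    """
    if not 0.0 < p_sig < p_ns < 1.0:
        raise ValueError("thresholds must satisfy 0 < p_sig < p_ns < 1")
    a = {c.gene_id: c for c in corr_A if c.ok and np.isfinite(c.p_value)}
    out = []
    for cb in corr_B:
        if not (cb.ok and np.isfinite(cb.p_value)):
            continue
        ca = a.get(cb.gene_id)
        if ca is None:
            continue
        if ca.p_value > p_ns and cb.p_value < p_sig:
            out.append(
                ImprovedGene(
                    gene_id=cb.gene_id,
                    coeff_A=ca.coefficient,
                    coeff_B=cb.coefficient,
                    p_A=ca.p_value,
                    p_B=cb.p_value,
                    direction=classify_direction(ca.coefficient, cb.coefficient),
                )
            )
    return out


def improved_frame(improved: Sequence[ImprovedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in improved],
            "coeff_A": [g.coeff_A for g in improved],
            "coeff_B": [g.coeff_B for g in improved],
            "p_A": [g.p_A for g in improved],
            "p_B": [g.p_B for g in improved],
            "direction": [g.direction for g in improved],
        }
    ).set_index("gene_id")
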
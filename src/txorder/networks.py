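"""Regulon-level analysis: mean regulatee expression and its growth correlation.

A regulator's network expression is the unweighted arithmetic mean of the
log10 expression of its regulatees (regulatory sign is ignored).  Only
networks with more than 15 regulatees present in the genome under study are
analysed; the same network may pass the size filter in the full-length
genome and fail it after genome reduction.  Per condition subset the mean
expression vector is correlated (Pearson) with growth rate, binned into a
0.2-wide coefficient histogram, and the significant networks (p < 0.05) are
tabulated with -log10 p.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConditionTable,
    ExpressionMatrix,
    NetworkCorrelation,
    RegulatoryNetwork,
    restrict_to_genome,
)
from ._stats import pearson_with_p

MIN_REGULATEES = 15  # "more than 15": networks of size >= 16 are kept
NETWORK_BIN_WIDTH = 0.2
SIGNIFICANCE_ALPHA = 0.05


def network_mean_expression(
    condition_matrix: ExpressionMatrix, network: RegulatoryNetwork
) -> tuple[pd.Series, int]:
    """Per-condition mean log10 expression over the network's regulatees.

    Missing values are excluded per condition; returns the mean vector and
    the number of regulatees present in the matrix.
    """
    present = [g for g in condition_matrix.gene_ids if g in network.regulatee_ids]
    if not present:
        raise ValueError(f"network {network.tf_id!r}: no regulatee present in the matrix")
    sub = condition_matrix.values.loc[present]
    return sub.mean(axis=0, skipna=True), len(present)


def select_networks(
    networks: Sequence[RegulatoryNetwork],
    present_genes: Iterable[str],
    min_regulatees: int = MIN_REGULATEES,
) -> list[RegulatoryNetwork]:
    """Restrict each network to the present genes, keep those with > min_regulatees."""
    present = set(present_genes)
    kept = []
    for net in networks:
        restricted = restrict_to_genome(net, present)
        if restricted.size > min_regulatees:
            kept.append(restricted)
    return kept


def network_growth_correlations(
    condition_matrix: ExpressionMatrix,
    conditions: ConditionTable,
    networks: Sequence[RegulatoryNetwork],
    subset_label: str = "all",
) -> list[NetworkCorrelation]:
    """Correlate each network's mean expression with growth rate over a subset.

    ``conditions`` should already be the desired subset (>= 3 conditions).
    Networks whose mean expression is constant over the subset come back
    flagged and are excluded from downstream histograms/tables.
    """
    cids = [c for c in conditions.condition_ids if c in condition_matrix.values.columns]
    if len(cids) < 3:
        raise ValueError(f"subset {subset_label!r} selects {len(cids)} conditions; need >= 3")
    sub = condition_matrix.subset_datasets(cids)
    y = conditions.growth_rates().loc[cids].to_numpy(dtype=float)
    out = []
    for net in networks:
        mean_expr, n_reg = network_mean_expression(sub, net)
        c, n, p, flag = pearson_with_p(mean_expr.to_numpy(dtype=float), y)
        out.append(
            NetworkCorrelation(
                tf_id=net.tf_id,
                subset_label=subset_label,
                coefficient=c,
                n=n,
                p_value=p,
                n_regulatees=n_reg,
                flag=flag,
            )
        )
    return out


def network_histogram(
    correlations: Sequence[NetworkCorrelation], bin_width: float = NETWORK_BIN_WIDTH
) -> pd.DataFrame:
    """Coefficient histogram over [-1, 1] (10 bins at the default width 0.2)."""
    n_bins = round(2.0 / bin_width)
    if not np.isclose(n_bins * bin_width, 2.0):
        raise ValueError(f"bin_width {bin_width} does not divide [-1, 1] evenly")
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    coeffs = np.array([c.coefficient for c in correlations if c.ok])
    counts, _ = np.histogram(coeffs, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def significance_table(
    correlations: Sequence[NetworkCorrelation], alpha: float = SIGNIFICANCE_ALPHA
) -> pd.DataFrame:
    """Networks with p < alpha, sorted by p, with -log10 p for gradient display."""
    rows = [
        {
            "tf_id": c.tf_id,
            "subset": c.subset_label,
            "coefficient": c.coefficient,
            "n": c.n,
            "n_regulatees": c.n_regulatees,
            "p_value": c.p_value,
            "neg_log10_p": float(-np.log10(max(c.p_value, np.finfo(float).tiny))),
        }
        for c in correlations
        if c.ok and np.isfinite(c.p_value) and c.p_value < alpha
    ]
    return (
        pd.DataFrame(
            rows,
            columns=[
                "tf_id",
                "subset",
                "coefficient",
                "n",
                "n_regulatees",
                "p_value",
                "neg_log10_p",
            ],
        )
        .sort_values("p_value")
        .set_index("tf_id")
    )
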
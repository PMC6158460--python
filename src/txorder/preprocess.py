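"""Detection filtering, global normalization, replicate averaging and clustering.

The stages mirror standard microarray mining practice: a gene is kept when
any measurement has a significant detection p-value; every data set is
shifted additively in log space to a common mean ("global normalization");
biological replicates are averaged into condition-level profiles; and
conditions are clustered agglomeratively (furthest-neighbour by default) on
Euclidean distances between log-expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ConditionTable, ExpressionMatrix

LINKAGES = ("complete", "average", "ward")


def filter_by_detection(matrix: ExpressionMatrix, alpha: float = 0.05) -> ExpressionMatrix:
    """Keep genes whose minimum detection p-value across data sets is < alpha.

    The surviving rows are returned with values untouched; only row
    membership changes.  Requires the matrix to carry detection p-values.
    """
    if matrix.detection_p is None:
        raise ValueError(
            "matrix has no detection p-values; skip the detection-filter stage "
            "explicitly if the input was pre-filtered"
        )
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    pmin = matrix.detection_p.min(axis=1, skipna=True)
    keep = pmin < alpha
    kept_genes = list(matrix.values.index[keep.to_numpy(dtype=bool)])
    return ExpressionMatrix(
        matrix.values.loc[kept_genes], matrix.detection_p.loc[kept_genes]
    )


def global_normalize(
    matrix: ExpressionMatrix, target_mean: Optional[float] = None
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Shift each data-set column additively so all column means coincide.

    In log scale an additive shift is a multiplicative rescaling of raw
    concentrations.  ``target_mean`` defaults to the grand mean of the
    pre-normalization column means.  Returns the normalized matrix and the
    per-column shifts applied.
    """
    means = matrix.values.mean(axis=0, skipna=True)
    all_missing = means.index[means.isna()]
    if len(all_missing):
        raise ValueError(f"dataset {all_missing[0]!r} has no non-missing values")
    if target_mean is None:
        target_mean = float(means.mean())
    shifts = (target_mean - means).astype(float)
    values = matrix.values.add(shifts, axis=1)
    return ExpressionMatrix(values, matrix.detection_p), dict(shifts)


def average_replicates(
    matrix: ExpressionMatrix, conditions: ConditionTable
) -> ExpressionMatrix:
    """Collapse replicate data sets into one column per condition.

    The condition profile is the arithmetic mean of the replicate columns in
    log scale (geometric mean of raw concentrations) over non-missing values.
    """
    conditions.validate_against(matrix)
    cols = {}
    for c in conditions:
        sub = matrix.values[list(c.replicate_dataset_ids)]
        cols[c.condition_id] = sub.mean(axis=1, skipna=True)
    out = pd.DataFrame(cols, index=matrix.values.index)
    out.index.name = "gene_id"
    return ExpressionMatrix(out)


@dataclass
class Dendrogram:
    """Agglomerative clustering result on condition profiles.

    ``linkage_matrix`` is the scipy ``(n-1) x 4`` encoding; ``labels`` are the
    condition ids in input order.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_partitions(self) -> list[frozenset[frozenset[str]]]:
        """Partition of the leaves after each successive merge (coarsening)."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        partitions = []
        next_id = len(self.labels)
        active = dict(clusters)
        for a, b, _, _ in self.linkage_matrix:
            merged = active.pop(int(a)) | active.pop(int(b))
            active[next_id] = merged
            next_id += 1
            partitions.append(frozenset(active.values()))
        return partitions

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        names = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            node = n + k
            heights[node] = float(h)
            la = heights[node] - heights[a]
            lb = heights[node] - heights[b]
            names[node] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
        return names[n + len(self.linkage_matrix) - 1] + ";"


def cluster_conditions(
    condition_matrix: ExpressionMatrix,
    linkage: str = "complete",
    gene_subset: Optional[Sequence[str]] = None,
) -> Dendrogram:
    """Agglomerative clustering of condition profiles.

    ``gene_subset`` defaults to the genes with no missing value in any
    condition (the cross-genome "common" gene set), so that all pairwise
    Euclidean distances are computed on identical coordinates.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if condition_matrix.n_datasets < 2:
        raise ValueError("clustering requires >= 2 conditions")
    values = condition_matrix.values
    if gene_subset is None:
        complete = values.dropna(axis=0, how="any")
    else:
        complete = values.loc[list(gene_subset)].dropna(axis=0, how="any")
    if complete.shape[0] == 0:
        raise ValueError("no genes without missing values to cluster on")
    profiles = complete.to_numpy(dtype=float).T  # conditions x genes
    dists = pdist(profiles, metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(Z, list(values.columns), linkage)
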
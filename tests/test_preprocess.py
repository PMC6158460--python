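"""Detection filtering, normalization, replicate averaging and clustering."""

import io as pyio
import itertools

import numpy as np
import pandas as pd
import pytest

from txorder.datamodel import (
    CellState,
    Condition,
    ConditionTable,
    ExpressionMatrix,
    GenomeClass,
)
from txorder.preprocess import (
    average_replicates,
    cluster_conditions,
    filter_by_detection,
    global_normalize,
)


def _matrix(values, pvals=None, genes=None, datasets=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    datasets = datasets or [f"d{j}" for j in range(values.shape[1])]
    v = pd.DataFrame(values, index=genes, columns=datasets)
    p = (
        pd.DataFrame(np.asarray(pvals, dtype=float), index=genes, columns=datasets)
        if pvals is not None
        else None
    )
    return ExpressionMatrix(v, p)


class TestDetectionFilter:
    def test_one_significant_measurement_keeps_gene(self):
        m = _matrix([[1, 2, 3]], pvals=[[0.04, 0.90, 0.80]])
        assert filter_by_detection(m).gene_ids == ["g0"]

    def test_never_detected_gene_removed(self):
        m = _matrix([[1, 2], [3, 4]], pvals=[[1.0, 1.0], [0.01, 0.9]])
        assert filter_by_detection(m).gene_ids == ["g1"]

    def test_random_matrix_matches_rowwise_min_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random((50, 8))
        m = _matrix(rng.normal(size=(50, 8)), pvals=p)
        kept = set(filter_by_detection(m, alpha=0.05).gene_ids)
        oracle = {f"g{i}" for i in range(50) if min(p[i]) < 0.05}
        assert kept == oracle

    def test_surviving_values_untouched(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(30, 4)), pvals=rng.random((30, 4)))
        out = filter_by_detection(m)
        assert out.values.equals(m.values.loc[out.gene_ids])

    def test_missing_pvalues_errors(self):
        with pytest.raises(ValueError, match="detection p-values"):
            filter_by_detection(_matrix([[1.0]]))


class TestGlobalNormalize:
    def test_explicit_target_shifts(self):
        m = _matrix([[0.5, 2.5], [1.5, 3.5]])  # column means 1.0 and 3.0
        out, shifts = global_normalize(m, target_mean=2.0)
        assert shifts == pytest.approx({"d0": 1.0, "d1": -1.0})
        assert out.values.mean().to_numpy() == pytest.approx([2.0, 2.0], abs=1e-9)

    def test_default_target_is_grand_mean_and_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(40, 5)) + rng.normal(scale=2, size=5)
        m = _matrix(vals)
        once, _ = global_normalize(m)
        twice, shifts2 = global_normalize(once)
        assert np.allclose(once.values, twice.values)
        assert max(abs(s) for s in shifts2.values()) < 1e-9
        target = m.values.mean().mean()
        assert np.allclose(once.values.mean(), target, atol=1e-9)

    def test_column_at_target_unchanged(self):
        m = _matrix([[1.0], [3.0]])  # mean 2.0
        out, shifts = global_normalize(m, target_mean=2.0)
        assert shifts["d0"] == 0.0
        assert out.values.equals(m.values)

    def test_all_missing_column_errors(self):
        m = _matrix([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="d1"):
            global_normalize(m)


def _conditions(groups):
    return ConditionTable(
        [
            Condition(cid, GenomeClass.FULL_LENGTH, CellState.STEADY, 0.5, tuple(reps))
            for cid, reps in groups.items()
        ]
    )


class TestAverageReplicates:
    def test_single_replicate_copied_verbatim(self):
        m = _matrix([[1.5], [2.5]])
        out = average_replicates(m, _conditions({"c1": ["d0"]}))
        assert list(out.values["c1"]) == [1.5, 2.5]

    def test_pairwise_means(self):
        vals = np.arange(12.0).reshape(2, 6)
        m = _matrix(vals)
        conds = _conditions({"c1": ["d0", "d1"], "c2": ["d2", "d3"], "c3": ["d4", "d5"]})
        out = average_replicates(m, conds)
        assert out.values.shape == (2, 3)
        assert list(out.values.loc["g0"]) == [0.5, 2.5, 4.5]
        assert list(out.values.loc["g1"]) == [6.5, 8.5, 10.5]

    def test_missing_aware_mean(self):
        m = _matrix([[1.0, np.nan, 3.0]])
        out = average_replicates(m, _conditions({"c": ["d0", "d1", "d2"]}))
        assert out.values.loc["g0", "c"] == 2.0

    def test_commutes_with_replicate_permutation(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(20, 4)))
        a = average_replicates(m, _conditions({"c": ["d0", "d1", "d2", "d3"]}))
        b = average_replicates(m, _conditions({"c": ["d3", "d1", "d0", "d2"]}))
        assert np.allclose(a.values, b.values)

    def test_unknown_dataset_errors(self):
        m = _matrix([[1.0]])
        with pytest.raises(ValueError, match="dX"):
            average_replicates(m, _conditions({"c": ["dX"]}))


def _complete_linkage_oracle(profiles: dict[str, np.ndarray]):
    """Exhaustive furthest-neighbour agglomeration; returns successive partitions."""
    clusters = {frozenset([k]): None for k in profiles}
    partitions = []
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a, b in itertools.combinations(clusters, 2):
            d = max(
                np.linalg.norm(profiles[i] - profiles[j]) for i in a for j in b
            )
            if d < best_d:
                best, best_d = (a, b), d
        a, b = best
        del clusters[a], clusters[b]
        clusters[a | b] = None
        partitions.append(frozenset(clusters.keys()))
    return partitions


class TestClusterConditions:
    def test_identical_profiles_merge_at_zero(self):
        m = _matrix(np.column_stack([np.arange(5.0), np.arange(5.0)]))
        dend = cluster_conditions(m)
        assert dend.linkage_matrix[0, 2] == 0.0

    def test_complete_linkage_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        # four well-separated profiles: no distance ties
        vals = np.column_stack(
            [
                rng.normal(0, 1, 30),
                rng.normal(0.5, 1, 30),
                rng.normal(5, 1, 30),
                rng.normal(9, 1, 30),
            ]
        )
        m = _matrix(vals)
        dend = cluster_conditions(m, linkage="complete")
        profiles = {c: vals[:, j] for j, c in enumerate(m.dataset_ids)}
        oracle = _complete_linkage_oracle(profiles)
        got = [
            frozenset(frozenset(cl) for cl in part)
            for part in dend.merge_partitions()
        ]
        assert got == [frozenset(p) for p in oracle]

    def test_leaf_set_is_conserved_and_newick_parses(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(25, 6)))
        dend = cluster_conditions(m, linkage="average")
        assert dend.labels == m.dataset_ids
        from Bio import Phylo

        tree = Phylo.read(pyio.StringIO(dend.to_newick()), "newick")
        assert {t.name for t in tree.get_terminals()} == set(m.dataset_ids)

    def test_default_gene_subset_drops_missing_rows(self):
        vals = np.ones((4, 3))
        vals[0, 1] = np.nan
        m = _matrix(vals)
        dend = cluster_conditions(m)  # rows with NaN excluded, no error
        assert dend.n_leaves == 3

    def test_fewer_than_two_conditions_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            cluster_conditions(_matrix([[1.0], [2.0]]))
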
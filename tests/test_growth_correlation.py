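"""Single-gene growth correlations, histograms and the improved-gene screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from txorder.datamodel import (
    CellState,
    Condition,
    ConditionTable,
    ExpressionMatrix,
    GeneGrowthCorrelation,
    GenomeClass,
)
from txorder.growth_correlation import (
    classify_direction,
    correlation_histogram,
    find_improved_genes,
    gene_growth_correlations,
)


def _setup(values, rates):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    conds = [f"c{j}" for j in range(values.shape[1])]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=conds))
    table = ConditionTable(
        [
            Condition(c, GenomeClass.FULL_LENGTH, CellState.STEADY, r, (f"d{j}",))
            for j, (c, r) in enumerate(zip(conds, rates))
        ]
    )
    return matrix, table


class TestGeneGrowthCorrelations:
    def test_perfectly_linear_gene(self):
        rates = np.linspace(0.1, 1.0, 10)
        matrix, table = _setup([0.5 * rates + 1.0], rates)
        (rec,) = gene_growth_correlations(matrix, table)
        assert rec.coefficient == pytest.approx(1.0)
        # an exactly perfect correlation has no finite t-statistic: flagged
        assert rec.flag == "perfect_correlation"

    def test_near_linear_gene_is_highly_significant(self):
        rates = np.linspace(0.1, 1.0, 10)
        noise = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1, -1]) * 1e-3
        matrix, table = _setup([0.5 * rates + 1.0 + noise], rates)
        (rec,) = gene_growth_correlations(matrix, table)
        assert rec.coefficient > 0.999
        assert rec.p_value < 1e-10

    def test_constant_gene_flagged(self):
        matrix, table = _setup([[2.0] * 5], np.linspace(0.1, 1.0, 5))
        (rec,) = gene_growth_correlations(matrix, table)
        assert rec.flag == "zero_variance"
        assert np.isnan(rec.coefficient)

    def test_sparse_gene_flagged_not_dropped(self):
        vals = np.full((2, 6), np.nan)
        vals[0] = np.linspace(1, 2, 6)
        vals[1, :2] = [1.0, 2.0]
        matrix, table = _setup(vals, np.linspace(0.1, 1.2, 6))
        recs = gene_growth_correlations(matrix, table)
        assert len(recs) == 2
        assert recs[1].flag == "n_too_small"

    def test_matches_scipy_pearson_on_random_genes(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        vals = rng.normal(size=(30, 12))
        rates = rng.uniform(0.1, 1.5, 12)
        matrix, table = _setup(vals, rates)
        for rec, row in zip(gene_growth_correlations(matrix, table), vals):
            r, p = stats.pearsonr(row, rates)
            assert rec.coefficient == pytest.approx(r, abs=1e-12)
            assert rec.p_value == pytest.approx(p, rel=1e-9)

    def test_too_few_conditions_errors(self):
        matrix, table = _setup([[1.0, 2.0]], [0.1, 0.2])
        with pytest.raises(ValueError, match="need >= 3"):
            gene_growth_correlations(matrix, table)

    def test_spearman_option_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        vals = rng.normal(size=(15, 10))
        vals[0, 3] = np.nan
        rates = rng.uniform(0.1, 1.5, 10)
        matrix, table = _setup(vals, rates)
        recs = gene_growth_correlations(matrix, table, method="spearman")
        for rec, row in zip(recs, vals):
            m = np.isfinite(row)
            rho, p = stats.spearmanr(row[m], rates[m])
            assert rec.coefficient == pytest.approx(rho, abs=1e-12)
            assert rec.p_value == pytest.approx(p, rel=1e-6)
        # spearman is invariant to monotone transforms of expression
        recs2 = gene_growth_correlations(
            _setup(vals * 3 + 1, rates)[0], table, method="spearman"
        )
        for a, b in zip(recs, recs2):
            assert a.coefficient == pytest.approx(b.coefficient)


def _recs(coeffs):
    return [
        GeneGrowthCorrelation(f"g{i}", "s", c, 10, 0.5)
        for i, c in enumerate(coeffs)
    ]


class TestCorrelationHistogram:
    def test_direct_binning(self):
        hist = correlation_histogram(_recs([-0.95, 0.05, 0.05, 1.0]))
        counts = dict(zip(hist["bin_left"].round(1), hist["count"]))
        assert counts[-1.0] == 1
        assert counts[0.0] == 2
        assert counts[0.9] == 1  # last bin is closed: coefficient 1.0 counted
        assert hist["count"].sum() == 4

    def test_conservation(self):
        rng = np.random.default_rng(4)
        recs = _recs(rng.uniform(-1, 1, 500))
        assert correlation_histogram(recs)["count"].sum() == 500

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(5)
        coeffs = rng.uniform(-1, 1, 1000)
        hist = correlation_histogram(_recs(coeffs))
        for left, right, count in hist.itertuples(index=False):
            if right == 1.0:
                expected = np.sum((coeffs >= left) & (coeffs <= right))
            else:
                expected = np.sum((coeffs >= left) & (coeffs < right))
            assert count == expected

    def test_flagged_records_excluded(self):
        recs = _recs([0.5]) + [
            GeneGrowthCorrelation("gx", "s", np.nan, 2, np.nan, "zero_variance")
        ]
        assert correlation_histogram(recs)["count"].sum() == 1

    def test_bad_bin_width_errors(self):
        with pytest.raises(ValueError, match="evenly"):
            correlation_histogram(_recs([0.0]), bin_width=0.3)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (-0.1, 0.7, "reverse"),  # sign flip
            (0.1, 0.8, "same"),  # strengthened positive
            (-0.3, -0.9, "same"),  # strengthened negative counts as same
            (0.0, 0.5, "same"),  # zero reference takes the focal sign
            (0.4, -0.2, "reverse"),
        ],
    )
    def test_cases(self, a, b, expected):
        assert classify_direction(a, b) == expected

    def test_undefined_coefficient_errors(self):
        with pytest.raises(ValueError, match="defined"):
            classify_direction(np.nan, 0.5)

    @given(
        st.floats(-1, 1, allow_nan=False), st.floats(-1, 1, allow_nan=False)
    )
    def test_reverse_iff_strict_sign_flip(self, a, b):
        out = classify_direction(a, b)
        if a * b > 0 or a == 0:
            assert out == "same"
        elif a * b < 0:
            assert out == "reverse"


def _corr_from_p(pairs, label):
    # coefficient sign alternates; magnitude irrelevant to the screen
    return [
        GeneGrowthCorrelation(f"g{i}", label, 0.5 if i % 2 else -0.5, 12, p)
        for i, p in enumerate(pairs)
    ]


class TestFindImprovedGenes:
    def test_printed_thresholds(self):
        a = _corr_from_p([0.5, 0.005], "A")
        b = _corr_from_p([1e-4, 1e-4], "B")
        out = find_improved_genes(a, b)
        assert [g.gene_id for g in out] == ["g0"]  # g1 fails p_A > 0.01

    def test_gene_in_only_one_subset_excluded(self):
        a = _corr_from_p([0.5], "A")
        b = _corr_from_p([1e-4, 1e-4], "B")
        assert len(find_improved_genes(a, b)) == 1

    def test_matches_double_threshold_scan_oracle(self):
        rng = np.random.default_rng(6)
        p_a = rng.random(200)
        p_b = 10 ** rng.uniform(-6, 0, 200)
        a = [GeneGrowthCorrelation(f"g{i}", "A", 0.1, 44, p) for i, p in enumerate(p_a)]
        b = [GeneGrowthCorrelation(f"g{i}", "B", 0.9, 12, p) for i, p in enumerate(p_b)]
        got = {g.gene_id for g in find_improved_genes(a, b, 0.01, 0.001)}
        oracle = {
            f"g{i}" for i in range(200) if p_a[i] > 0.01 and p_b[i] < 0.001
        }
        assert got == oracle

    def test_direction_carried_through(self):
        a = [GeneGrowthCorrelation("g", "A", -0.2, 44, 0.5)]
        b = [GeneGrowthCorrelation("g", "B", 0.95, 12, 1e-5)]
        (out,) = find_improved_genes(a, b)
        assert out.direction == "reverse"
        assert out.coeff_A == -0.2 and out.coeff_B == 0.95

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_sig < p_ns"):
            find_improved_genes([], [], p_ns=0.001, p_sig=0.01)


class TestZeroGrowthRemoval:
    def test_subsets_without_zero_growth_are_unchanged(self, default_study):
        # recomputing after removing zero-growth conditions only changes
        # records whose subset contained those conditions
        conds = default_study.conditions
        steady = conds.select(genome_class=GenomeClass.FULL_LENGTH, state=CellState.STEADY)
        assert all(c.growth_rate > 0 for c in steady)
        from txorder.preprocess import average_replicates

        cm = average_replicates(default_study.expression, conds)
        sub = cm.subset_datasets(steady.condition_ids)
        with_zero = gene_growth_correlations(sub, steady, "st")
        without = gene_growth_correlations(
            sub, steady.select(exclude_zero_growth=True), "st"
        )
        for x, y in zip(with_zero, without):
            assert x == y
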
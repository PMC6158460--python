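"""End-to-end orchestration of the transcriptome-order analysis.

Stage order mirrors the underlying study design: per-genome-class detection
filtering, global normalization, replicate averaging, condition clustering,
per-condition power-law fits with group comparisons, single-gene growth
correlation screens (full-length vs. reduced genome; all conditions vs.
steady state), direction-resolved category enrichment, and regulon-level
growth correlations.  All thresholds live in :class:`PipelineParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import io as txio
from .datamodel import (
    CellState,
    ConditionTable,
    ExpressionMatrix,
    GeneAnnotation,
    GenomeClass,
    RegulatoryNetwork,
)
from .preprocess import (
    average_replicates,
    cluster_conditions,
    filter_by_detection,
    global_normalize,
)
from .powerlaw import (
    DEFAULT_FIT_RANGE,
    compare_slope_groups,
    correlate_slopes_with_growth,
    empirical_cumulative,
    fit_power_law,
)
from .growth_correlation import (
    correlation_histogram,
    correlations_frame,
    find_improved_genes,
    gene_growth_correlations,
    improved_frame,
)
from .enrichment import enrichment_by_direction
from .networks import (
    network_growth_correlations,
    network_histogram,
    select_networks,
    significance_table,
)


@dataclass
class PipelineParams:
    """All tunable thresholds, with the conventional values as defaults."""

    detection_alpha: float = 0.05
    target_mean: Optional[float] = None  # None: grand mean of column means
    linkage: str = "complete"
    fit_range_log10: tuple[float, float] = DEFAULT_FIT_RANGE
    p_ns: float = 0.01  # "no correlation" threshold in the reference subset
    p_sig: float = 0.001  # "high correlation" threshold in the focal subset
    gene_bin_width: float = 0.1
    network_bin_width: float = 0.2
    min_category_size: int = 15  # strictly more than 15 genes
    min_regulatees: int = 15  # strictly more than 15 regulatees
    network_alpha: float = 0.05
    exclude_zero_growth: bool = False
    mask_to_common_genes: bool = False  # gray-line control of the gene screen
    skip_detection_filter: bool = False


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, plus a JSON-ready summary."""

    params: PipelineParams
    condition_matrix: ExpressionMatrix
    normalization_shifts: dict[str, float]
    genes_full: list[str]
    genes_reduced: list[str]
    dendrogram_newick: str
    fits: list  # PowerLawFit per condition
    slope_by_genome: object  # SlopeGroupComparison
    slope_by_state: object
    slope_growth_correlation: object  # GeneGrowthCorrelation record
    correlations: dict[str, list]  # subset label -> GeneGrowthCorrelation list
    histograms: dict[str, pd.DataFrame]
    improved: dict[str, list]  # screen label -> ImprovedGene list
    enrichment_grids: dict[str, pd.DataFrame]
    network_correlations: dict[str, list]
    network_histograms: dict[str, pd.DataFrame]
    network_significant: dict[str, pd.DataFrame]

    def summary(self) -> dict:
        def _counts(improved):
            return {
                "total": len(improved),
                "same": sum(1 for g in improved if g.direction == "same"),
                "reverse": sum(1 for g in improved if g.direction == "reverse"),
            }

        slopes = [f.slope_r for f in self.fits]
        return {
            "n_conditions": len(self.fits),
            "n_genes_full": len(self.genes_full),
            "n_genes_reduced": len(self.genes_reduced),
            "n_genes_common": len(set(self.genes_full) & set(self.genes_reduced)),
            "slope_range": [float(min(slopes)), float(max(slopes))],
            "slope_mean_by_genome": self.slope_by_genome.group_means,
            "slope_genome_p": min(self.slope_by_genome.pairwise_p.values()),
            "slope_mean_by_state": self.slope_by_state.group_means,
            "slope_state_p": min(self.slope_by_state.pairwise_p.values()),
            "slope_growth_correlation_p": self.slope_growth_correlation.p_value,
            "improved_gene_counts": {k: _counts(v) for k, v in self.improved.items()},
            "top_enriched_category": {
                screen: _top_enriched(grid) for screen, grid in self.enrichment_grids.items()
            },
            "significant_networks": {
                k: list(df.index) for k, df in self.network_significant.items()
            },
            "exclude_zero_growth": self.params.exclude_zero_growth,
        }


def _top_enriched(grid: pd.DataFrame) -> dict:
    both = grid.xs("both", level="direction")
    cat = both["p_value"].idxmin()
    return {"category": str(cat), "p_value": float(both.loc[cat, "p_value"])}


def run_full_analysis(
    expression: ExpressionMatrix,
    conditions: ConditionTable,
    annotation: GeneAnnotation,
    networks: Sequence[RegulatoryNetwork],
    params: Optional[PipelineParams] = None,
) -> AnalysisResult:
    """Run every analysis stage on one study (measured or simulated)."""
    params = params or PipelineParams()
    conditions.validate_against(expression)

    # --- stage 1: detection filter, applied per genome class -------------
    # A gene enters a class's analyses when any measurement in that class's
    # arrays detects it (p < alpha); deleted genes carry no measurements in
    # reduced-genome arrays and drop out of the reduced set automatically.
    by_class: dict[GenomeClass, list[str]] = {}
    for gclass in (GenomeClass.FULL_LENGTH, GenomeClass.REDUCED):
        sub_conditions = conditions.select(genome_class=gclass)
        datasets = [d for c in sub_conditions for d in c.replicate_dataset_ids]
        if not datasets:
            by_class[gclass] = []
            continue
        class_matrix = expression.subset_datasets(datasets)
        if params.skip_detection_filter or expression.detection_p is None:
            kept = [
                g
                for g, ok in class_matrix.values.notna().any(axis=1).items()
                if ok
            ]
        else:
            kept = filter_by_detection(class_matrix, params.detection_alpha).gene_ids
        by_class[gclass] = kept
    genes_full = by_class[GenomeClass.FULL_LENGTH]
    genes_reduced = by_class[GenomeClass.REDUCED]
    union = sorted(set(genes_full) | set(genes_reduced))
    filtered = expression.subset_genes(union)

    # --- stage 2-3: normalization and replicate averaging ----------------
    normalized, shifts = global_normalize(filtered, params.target_mean)
    condition_matrix = average_replicates(normalized, conditions)

    # --- stage 4: condition clustering on the common gene set ------------
    dendro = cluster_conditions(condition_matrix, linkage=params.linkage)

    # --- stage 5: power-law fits and group comparisons --------------------
    analysis_conditions = conditions.select(
        exclude_zero_growth=params.exclude_zero_growth
    )
    fits = []
    for c in analysis_conditions:
        class_genes = by_class[c.genome_class]
        vec = condition_matrix.values.loc[class_genes, c.condition_id].to_numpy()
        fits.append(
            fit_power_law(
                empirical_cumulative(vec), params.fit_range_log10, c.condition_id
            )
        )
    genome_grouping = {
        c.condition_id: c.genome_class.value for c in analysis_conditions
    }
    state_grouping = {c.condition_id: c.state.value for c in analysis_conditions}
    slope_by_genome = compare_slope_groups(fits, genome_grouping)
    slope_by_state = compare_slope_groups(fits, state_grouping)
    slope_growth = correlate_slopes_with_growth(fits, analysis_conditions)

    # --- stage 6: single-gene growth correlations -------------------------
    ezg = params.exclude_zero_growth
    subsets = {
        "FL_all": (
            conditions.select(genome_class=GenomeClass.FULL_LENGTH, exclude_zero_growth=ezg),
            genes_full,
        ),
        "FL_steady": (
            conditions.select(
                genome_class=GenomeClass.FULL_LENGTH,
                state=CellState.STEADY,
                exclude_zero_growth=ezg,
            ),
            genes_full,
        ),
        "RD_all": (
            conditions.select(genome_class=GenomeClass.REDUCED, exclude_zero_growth=ezg),
            genes_reduced,
        ),
    }
    if params.mask_to_common_genes:
        common = sorted(set(genes_full) & set(genes_reduced))
        subsets["FL_all_common"] = (subsets["FL_all"][0], common)
    correlations: dict[str, list] = {}
    histograms: dict[str, pd.DataFrame] = {}
    for label, (sub_conditions, gene_set) in subsets.items():
        sub_matrix = condition_matrix.subset_genes(gene_set).subset_datasets(
            sub_conditions.condition_ids
        )
        corr = gene_growth_correlations(sub_matrix, sub_conditions, subset_label=label)
        correlations[label] = corr
        histograms[label] = correlation_histogram(corr, params.gene_bin_width)

    # --- stage 7: improved-correlation screens and enrichment -------------
    screens = {
        "reduced": ("FL_all", "RD_all"),
        "steady": ("FL_all", "FL_steady"),
    }
    improved: dict[str, list] = {}
    grids: dict[str, pd.DataFrame] = {}
    for screen, (ref, focal) in screens.items():
        imp = find_improved_genes(
            correlations[ref], correlations[focal], params.p_ns, params.p_sig
        )
        improved[screen] = imp
        background = genes_reduced if screen == "reduced" else genes_full
        grids[screen] = enrichment_by_direction(
            imp, annotation, params.min_category_size, background=background
        )

    # --- stage 8: regulon-level correlations ------------------------------
    nets_by_class = {
        GenomeClass.FULL_LENGTH: select_networks(
            networks, genes_full, params.min_regulatees
        ),
        GenomeClass.REDUCED: select_networks(
            networks, genes_reduced, params.min_regulatees
        ),
    }
    net_subsets = {
        "FL_all": (subsets["FL_all"][0], GenomeClass.FULL_LENGTH),
        "FL_steady": (subsets["FL_steady"][0], GenomeClass.FULL_LENGTH),
        "RD_all": (subsets["RD_all"][0], GenomeClass.REDUCED),
    }
    net_corr: dict[str, list] = {}
    net_hist: dict[str, pd.DataFrame] = {}
    net_sig: dict[str, pd.DataFrame] = {}
    for label, (sub_conditions, gclass) in net_subsets.items():
        nets = nets_by_class[gclass]
        corr = network_growth_correlations(
            condition_matrix, sub_conditions, nets, subset_label=label
        )
        net_corr[label] = corr
        net_hist[label] = network_histogram(corr, params.network_bin_width)
        net_sig[label] = significance_table(corr, params.network_alpha)

    return AnalysisResult(
        params=params,
        condition_matrix=condition_matrix,
        normalization_shifts=shifts,
        genes_full=genes_full,
        genes_reduced=genes_reduced,
        dendrogram_newick=dendro.to_newick(),
        fits=fits,
        slope_by_genome=slope_by_genome,
        slope_by_state=slope_by_state,
        slope_growth_correlation=slope_growth,
        correlations=correlations,
        histograms=histograms,
        improved=improved,
        enrichment_grids=grids,
        network_correlations=net_corr,
        network_histograms=net_hist,
        network_significant=net_sig,
    )


def write_result(result: AnalysisResult, out_dir: Union[str, Path]) -> dict:
    """Write every stage artifact under ``out_dir``; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txio.write_expression_matrix(result.condition_matrix, out / "condition_matrix.tsv")
    (out / "dendrogram.nwk").write_text(result.dendrogram_newick + "\n")
    pd.DataFrame(
        [
            {
                "condition_id": f.condition_id,
                "slope_r": f.slope_r,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
            }
            for f in result.fits
        ]
    ).to_csv(out / "powerlaw_fits.tsv", sep="\t", index=False)
    for label, corr in result.correlations.items():
        correlations_frame(corr).to_csv(out / f"gene_correlations_{label}.tsv", sep="\t")
        result.histograms[label].to_csv(
            out / f"gene_histogram_{label}.tsv", sep="\t", index=False
        )
    for screen, imp in result.improved.items():
        improved_frame(imp).to_csv(out / f"improved_genes_{screen}.tsv", sep="\t")
        result.enrichment_grids[screen].to_csv(out / f"enrichment_{screen}.tsv", sep="\t")
    for label, corr in result.network_correlations.items():
        pd.DataFrame(
            [
                {
                    "tf_id": c.tf_id,
                    "coefficient": c.coefficient,
                    "n": c.n,
                    "p_value": c.p_value,
                    "n_regulatees": c.n_regulatees,
                    "flag": c.flag,
                }
                for c in corr
            ]
        ).to_csv(out / f"network_correlations_{label}.tsv", sep="\t", index=False)
        result.network_histograms[label].to_csv(
            out / f"network_histogram_{label}.tsv", sep="\t", index=False
        )
        result.network_significant[label].to_csv(
            out / f"network_significant_{label}.tsv", sep="\t"
        )
    summary = result.summary()
    summary["normalization_shifts"] = {
        k: float(v) for k, v in result.normalization_shifts.items()
    }
    txio.write_json(summary, out / "summary.json")
    return summary
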
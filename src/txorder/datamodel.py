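"""Domain types shared by every stage of the pipeline.

The central containers are :class:`ExpressionMatrix` (genes x data sets of
log10 expression, optionally paired with per-measurement detection
p-values), :class:`ConditionTable` (experimental metadata: genome class,
cellular state, growth rate, replicate grouping) and
:class:`RegulatoryNetwork` (a regulator and its regulatees).  Result records
(power-law fits, growth correlations, enrichment rows) are plain frozen
dataclasses so they serialize trivially to TSV/JSON.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeClass",
    "CellState",
    "ExpressionMatrix",
    "Condition",
    "ConditionTable",
    "GeneAnnotation",
    "RegulatoryNetwork",
    "PowerLawFit",
    "GeneGrowthCorrelation",
    "ImprovedGene",
    "EnrichmentResult",
    "NetworkCorrelation",
    "restrict_to_genome",
]


class GenomeClass(str, enum.Enum):
    """Genome size category: full-length wild type vs. engineered reduced genome."""

    FULL_LENGTH = "full_length"
    REDUCED = "reduced"


class CellState(str, enum.Enum):
    """Cellular state: exponentially growing (steady) vs. responsive (unsteady)."""

    STEADY = "steady"
    UNSTEADY = "unsteady"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Log10 expression values for genes (rows) across microarray data sets (columns).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per data set.  Entries
        are log10 mRNA concentrations; missing measurements are NaN, never
        silently zero.
    detection_p
        Optional DataFrame of identical shape holding per-measurement
        detection p-values in [0, 1].
    """

    values: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene_id")
        _check_unique(list(self.values.columns), "dataset_id")
        self.values = self.values.astype(float)
        if self.detection_p is not None:
            p = self.detection_p
            if p.shape != self.values.shape:
                raise ValueError(
                    f"detection_p shape {p.shape} does not match values shape "
                    f"{self.values.shape}"
                )
            if list(p.index) != list(self.values.index) or list(p.columns) != list(
                self.values.columns
            ):
                raise ValueError("detection_p gene/dataset ids differ from values")
            arr = p.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("detection p-values must lie in [0, 1]")
            self.detection_p = p.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_datasets(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = [g for g in self.values.index if g in set(gene_ids)]
        p = self.detection_p.loc[idx] if self.detection_p is not None else None
        return ExpressionMatrix(self.values.loc[idx], p)

    def subset_datasets(self, dataset_ids: Sequence[str]) -> "ExpressionMatrix":
        cols = list(dataset_ids)
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise KeyError(f"unknown dataset ids: {missing}")
        p = self.detection_p[cols] if self.detection_p is not None else None
        return ExpressionMatrix(self.values[cols], p)

    def equals(self, other: "ExpressionMatrix") -> bool:
        same_v = self.values.equals(other.values)
        if self.detection_p is None and other.detection_p is None:
            return same_v
        if (self.detection_p is None) != (other.detection_p is None):
            return False
        return same_v and self.detection_p.equals(other.detection_p)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: metadata plus its biological replicates."""

    condition_id: str
    genome_class: GenomeClass
    state: CellState
    growth_rate: float  # specific growth rate, h^-1; 0 by convention for paused growth
    replicate_dataset_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError(
                f"condition {self.condition_id}: growth_rate must be >= 0"
            )
        if not self.replicate_dataset_ids:
            raise ValueError(f"condition {self.condition_id}: no replicates")
        _check_unique(self.replicate_dataset_ids, "replicate dataset_id")


class ConditionTable:
    """Ordered collection of :class:`Condition` records.

    Replicate lists must be disjoint across conditions.  Provides the subset
    selectors used throughout the analysis (genome class, cellular state,
    exclusion of zero-growth conditions).
    """

    def __init__(self, conditions: Sequence[Condition]):
        _check_unique([c.condition_id for c in conditions], "condition_id")
        seen: dict[str, str] = {}
        for c in conditions:
            for d in c.replicate_dataset_ids:
                if d in seen:
                    raise ValueError(
                        f"dataset {d!r} appears in conditions "
                        f"{seen[d]!r} and {c.condition_id!r}"
                    )
                seen[d] = c.condition_id
        self.conditions: tuple[Condition, ...] = tuple(conditions)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    def growth_rates(self) -> pd.Series:
        return pd.Series(
            {c.condition_id: c.growth_rate for c in self.conditions},
            name="growth_rate",
        ).loc[self.condition_ids]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.dataset_ids)
        for c in self.conditions:
            unknown = [d for d in c.replicate_dataset_ids if d not in known]
            if unknown:
                raise ValueError(
                    f"condition {c.condition_id}: unknown dataset ids {unknown}"
                )

    def select(
        self,
        genome_class: Optional[GenomeClass] = None,
        state: Optional[CellState] = None,
        exclude_zero_growth: bool = False,
    ) -> "ConditionTable":
        kept = [
            c
            for c in self.conditions
            if (genome_class is None or c.genome_class == genome_class)
            and (state is None or c.state == state)
            and not (exclude_zero_growth and c.growth_rate == 0.0)
        ]
        return ConditionTable(kept)


@dataclass
class GeneAnnotation:
    """Functional-category annotation plus reduced-genome presence flags.

    ``table`` is indexed by gene id with columns ``category`` (one of a
    finite vocabulary, 20 classes in the full-length annotation) and
    ``in_reduced`` (bool: the gene survives genome reduction).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "annotated gene_id")
        required = {"category", "in_reduced"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table["category"] = self.table["category"].astype(str)
        self.table["in_reduced"] = self.table["in_reduced"].astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def categories(self) -> list[str]:
        return sorted(self.table["category"].unique())

    def category_of(self) -> pd.Series:
        return self.table["category"]

    def reduced_gene_ids(self) -> set[str]:
        return set(self.table.index[self.table["in_reduced"]])


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A transcriptional regulator (TF or sigma factor) and its regulatees."""

    tf_id: str
    regulatee_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.regulatee_ids, frozenset):
            object.__setattr__(self, "regulatee_ids", frozenset(self.regulatee_ids))

    @property
    def size(self) -> int:
        return len(self.regulatee_ids)


def restrict_to_genome(
    network: RegulatoryNetwork, present_genes: Iterable[str]
) -> RegulatoryNetwork:
    """Intersect a network's regulatees with the genes present in a genome.

    Regulatee sets shrink when genes are deleted; the TF label is retained
    even if the regulator's own gene is absent.  An empty intersection yields
    an empty network (callers filter on size).
    """
    return RegulatoryNetwork(network.tf_id, frozenset(network.regulatee_ids) & set(present_genes))


@dataclass(frozen=True)
class PowerLawFit:
    """Cumulative power-law exponent fitted for one condition.

    ``slope_r`` is minus the log-log regression slope of the cumulative
    distribution, hence positive for a decaying distribution.
    """

    condition_id: str
    slope_r: float
    intercept: float
    fit_range_log10: tuple[float, float]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("power-law fit requires >= 3 regression points")


@dataclass(frozen=True)
class GeneGrowthCorrelation:
    """Pearson correlation of one gene's log expression against growth rate."""

    gene_id: str
    subset_label: str
    coefficient: float  # NaN when degenerate (flagged)
    n: int
    p_value: float  # NaN when undefined (n < 3 or |coefficient| == 1)
    flag: str = ""  # empty when the record is usable

    @property
    def ok(self) -> bool:
        return self.flag == "" and np.isfinite(self.coefficient)


@dataclass(frozen=True)
class ImprovedGene:
    """A gene non-correlated in the reference subset but highly correlated in the focal one."""

    gene_id: str
    coeff_A: float
    coeff_B: float
    p_A: float
    p_B: float
    direction: str  # "same" or "reverse"


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided binomial over-representation result for one gene category."""

    category: str
    n_selected_in_category: int
    n_selected: int
    category_size: int
    genome_size: int
    p_value: float
    flag: str = ""

    def __post_init__(self) -> None:
        if self.n_selected_in_category > min(self.n_selected, self.category_size):
            raise ValueError("selected-in-category count exceeds its bounds")

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(max(self.p_value, np.finfo(float).tiny)))


@dataclass(frozen=True)
class NetworkCorrelation:
    """Correlation of a regulon's mean expression with growth rate over a subset."""

    tf_id: str
    subset_label: str
    coefficient: float
    n: int
    p_value: float
    n_regulatees: int
    flag: str = ""

    @property
    def ok(self) -> bool:
        return self.flag == "" and np.isfinite(self.coefficient)
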
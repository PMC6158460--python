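"""Synthetic transcriptome studies with the statistical structure the pipeline assumes.

The generator emulates a multi-condition bulk-microarray compendium: a
power-law (Zipf) distributed expression background, conditions categorized
by genome class (full-length vs. reduced) and cellular state (steady vs.
unsteady), biological replicates with log-scale noise, per-measurement
detection p-values, a planted subset of genes whose log expression is
linearly coupled to growth rate within a declared stratum, functional
categories, and TF regulons some of which are built entirely from coupled
genes.  Truth tables identify every planted feature so recovery can be
scored end to end.

Everything is driven by one :class:`SimulationConfig` and a single seed;
identical configs yield byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    CellState,
    Condition,
    ConditionTable,
    ExpressionMatrix,
    GeneAnnotation,
    GenomeClass,
    RegulatoryNetwork,
)
from . import io as txio

# Riley-style functional classification labels (20 classes, as in the
# full-length E. coli annotation).
CATEGORY_NAMES = (
    "Enzyme",
    "Factor",
    "Transporter",
    "Membrane",
    "Regulator",
    "Carrier",
    "RNA",
    "Cell structure",
    "Cell process",
    "Phage",
    "IS element",
    "Transcription",
    "Translation",
    "Replication",
    "Energy metabolism",
    "Amino acid metabolism",
    "Nucleotide metabolism",
    "Lipoprotein",
    "Putative enzyme",
    "Unknown",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_study`.

    Defaults reproduce the design of the compendium the pipeline targets:
    56 conditions (44 full-length of which 23 steady, 12 reduced of which 11
    steady), 168-ish arrays from 2-7 biological replicates per condition,
    cumulative exponents inside the 2.2-2.8 band with the reduced genome
    shifted upward, 16 zero-growth unsteady conditions, ~20% of genes deleted
    by genome reduction, 150 planted growth-coupled genes and 5 regulons
    built from them.
    """

    n_genes: int = 3000
    # cumulative exponent per genome class (full_length, reduced); a scalar
    # applies to both classes
    r_true: Union[float, tuple[float, float]] = (2.4, 2.7)
    r_sd: float = 0.05  # per-condition jitter of the exponent
    k_min_log10: float = -1.0
    # conditions per (genome_class, state) cell
    n_conditions: dict = field(
        default_factory=lambda: {
            ("full_length", "steady"): 23,
            ("full_length", "unsteady"): 21,
            ("reduced", "steady"): 11,
            ("reduced", "unsteady"): 1,
        }
    )
    growth_rate_range: tuple[float, float] = (0.1, 1.5)  # steady states, h^-1
    unsteady_growth_range: tuple[float, float] = (0.05, 0.8)  # non-paused unsteady
    zero_growth_fraction: float = 16 / 22  # fraction of unsteady conditions paused
    n_coupled: int = 150
    coupling_slope: float = 1.5  # rank-score shift (log10 units) per h^-1
    # coupled genes are drawn from the upper part of the baseline
    # distribution: genes at the power-law floor have no downward dynamic
    # range (as at a detection floor in real data), so growth-coupled genes
    # are planted among reasonably expressed genes
    coupled_baseline_quantile: float = 0.6
    # fraction of coupled genes with negative coupling; 0.5 balances the
    # planted signal so rank conservation does not induce a compensating
    # opposite trend in every uncoupled gene (compositional closure)
    coupled_negative_fraction: float = 0.5
    coupled_stratum: str = "reduced"  # "reduced" or "steady_full"
    condition_sd: float = 0.15  # condition-level biological variation, log10
    noise_sd: float = 0.1  # replicate noise, log10
    n_replicates: tuple[int, int] = (2, 7)
    n_categories: int = 20
    coupled_category: str = "Enzyme"
    coupled_category_prob: float = 0.5  # planted enrichment strength
    n_networks: int = 40
    n_coupled_networks: int = 5
    regulatees_per_network: tuple[int, int] = (16, 120)
    coupled_regulon_size: tuple[int, int] = (16, 24)
    deleted_fraction: float = 0.22
    dropout_fraction: float = 0.04  # genes below detection on every array
    response_fraction: float = 0.10  # genes with an unsteady "response" signature
    response_sd: float = 0.3  # per-gene response magnitude, log10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_coupled < 0 or self.n_networks < 0:
            raise ValueError("counts must be positive")
        r = self.r_true if isinstance(self.r_true, tuple) else (self.r_true, self.r_true)
        if min(r) <= 1.0:
            raise ValueError("r_true must exceed 1 (finite-mean regime)")
        if not 0.0 <= self.deleted_fraction < 1.0:
            raise ValueError("deleted_fraction must lie in [0, 1)")
        if self.n_coupled > self.n_genes:
            raise ValueError("n_coupled exceeds n_genes")
        if self.coupled_stratum not in ("reduced", "steady_full"):
            raise ValueError(f"unknown coupled_stratum {self.coupled_stratum!r}")
        if self.n_coupled_networks > self.n_networks:
            raise ValueError("n_coupled_networks exceeds n_networks")
        n_neg = int(round(self.coupled_negative_fraction * self.n_coupled))
        n_pos = self.n_coupled - n_neg
        need_pos = -(-self.n_coupled_networks // 2) * self.coupled_regulon_size[1]
        need_neg = (self.n_coupled_networks // 2) * self.coupled_regulon_size[1]
        if need_pos > max(n_pos, 1) or need_neg > max(n_neg, 1):
            raise ValueError(
                "coupled regulons cannot be built sign-coherently from the "
                "coupled gene set"
            )
        if not 1 < self.n_categories <= len(CATEGORY_NAMES):
            raise ValueError(f"n_categories must be in [2, {len(CATEGORY_NAMES)}]")

    def r_for(self, genome_class: GenomeClass) -> float:
        if isinstance(self.r_true, tuple):
            return self.r_true[0 if genome_class is GenomeClass.FULL_LENGTH else 1]
        return float(self.r_true)


def simulate_expression_powerlaw(
    n_genes: int,
    r_true: float,
    k_min_log10: float = -1.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Draw log10 expression levels whose cumulative distribution is K^(-r).

    Inverse-CDF sampling of a Pareto law with lower cutoff K_min:
    K = K_min * U**(-1/r), i.e. log10 K = k_min_log10 - log10(U)/r.  The
    uniforms are stratified (Latin hypercube: one jittered draw per 1/n
    stratum, in random order), so each value is marginally Pareto while the
    realized cumulative curve tracks K^(-r) closely even at moderate n —
    the planted exponent is genuinely true of the generated sample.
    """
    if r_true <= 1.0:
        raise ValueError("r_true must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = _stratified_uniform(n_genes, rng)
    return k_min_log10 - np.log10(u) / r_true


def _stratified_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    """One Uniform draw per 1/n stratum, shuffled; marginally Uniform(0,1)."""
    return (rng.permutation(n) + rng.random(n)) / n


@dataclass
class StudyTruth:
    """Planted features of a synthetic study, for recovery scoring."""

    coupled_genes: tuple[str, ...]
    deleted_genes: tuple[str, ...]
    dropout_genes: tuple[str, ...]
    response_genes: tuple[str, ...]
    coupled_tfs: tuple[str, ...]
    r_by_condition: dict[str, float]
    # noiseless condition-level profiles (genes x conditions), before
    # replicate noise; deleted genes are NaN in reduced-genome conditions
    condition_profiles: Optional[pd.DataFrame] = None


@dataclass
class SyntheticStudy:
    """Complete generated bundle: data, metadata, annotation, networks, truth."""

    expression: ExpressionMatrix  # genes x arrays, with detection p-values
    conditions: ConditionTable
    annotation: GeneAnnotation
    networks: list[RegulatoryNetwork]
    truth: StudyTruth
    config: SimulationConfig

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        txio.write_expression_matrix(
            self.expression, out / "expression.tsv", out / "detection_p.tsv"
        )
        txio.write_condition_table(self.conditions, out / "conditions.tsv")
        txio.write_annotation(self.annotation, out / "annotation.tsv")
        txio.write_network_file(self.networks, out / "network.tsv")
        pd.DataFrame({"gene_id": list(self.truth.coupled_genes)}).to_csv(
            out / "coupled_genes.tsv", sep="\t", index=False
        )
        pd.DataFrame({"tf_id": list(self.truth.coupled_tfs)}).to_csv(
            out / "coupled_networks.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene_id": list(self.truth.deleted_genes)}).to_csv(
            out / "deleted_genes.tsv", sep="\t", index=False
        )


def _make_conditions(cfg: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Condition skeletons: id, class, state, growth rate (replicates later)."""
    conds = []
    for (gclass, state), count in cfg.n_conditions.items():
        gclass_e, state_e = GenomeClass(gclass), CellState(state)
        prefix = ("FL" if gclass_e is GenomeClass.FULL_LENGTH else "RD") + (
            "_st" if state_e is CellState.STEADY else "_un"
        )
        # growth rates are stratified over their range: a compendium's
        # conditions are chosen to span slow to fast growth by design
        if state_e is CellState.STEADY:
            lo, hi = cfg.growth_rate_range
            rates = lo + (hi - lo) * _stratified_uniform(count, rng)
            zero = np.zeros(count, dtype=bool)
        else:
            n_zero = int(round(cfg.zero_growth_fraction * count))
            lo, hi = cfg.unsteady_growth_range
            rates = lo + (hi - lo) * _stratified_uniform(count, rng)
            zero = np.zeros(count, dtype=bool)
            zero[:n_zero] = True
            rates[zero] = 0.0
        for i in range(count):
            conds.append(
                {
                    "condition_id": f"{prefix}_{i + 1:02d}",
                    "genome_class": gclass_e,
                    "state": state_e,
                    "growth_rate": float(rates[i]),
                    "zero_growth": bool(zero[i]),
                }
            )
    return conds


def simulate_study(config: Optional[SimulationConfig] = None) -> SyntheticStudy:
    """Generate a full synthetic study from one config (deterministic per seed).

    Construction, in order: a shared uniform quantile per gene maps through
    each condition's exponent (class exponent + jitter) so every condition's
    marginal is an exact power law while gene ranks are preserved across
    conditions; condition-level Gaussian variation is added on top; planted
    coupled genes receive a mean-centred additive shift of
    ``coupling_slope * growth_rate`` inside the declared stratum; unsteady
    conditions carry a per-gene "response" signature (full strength at zero
    growth, half strength otherwise); genes deleted by genome reduction are
    missing in reduced-class arrays; replicates add Gaussian noise; detection
    p-values are small for expressed genes and above the significance cutoff
    for dropout genes.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = np.array([f"G{i + 1:04d}" for i in range(cfg.n_genes)])
    u = _stratified_uniform(cfg.n_genes, rng)  # shared quantiles -> rank preservation

    # --- planted gene sets (drawn in a fixed order for determinism) ---
    n_dropout = int(round(cfg.dropout_fraction * cfg.n_genes))
    dropout_idx = rng.choice(cfg.n_genes, size=n_dropout, replace=False)
    is_dropout = np.zeros(cfg.n_genes, dtype=bool)
    is_dropout[dropout_idx] = True

    # u is the gene's upper-tail quantile: small u = high baseline expression
    eligible = np.flatnonzero(~is_dropout & (u < cfg.coupled_baseline_quantile))
    coupled_idx = rng.choice(eligible, size=cfg.n_coupled, replace=False)
    is_coupled = np.zeros(cfg.n_genes, dtype=bool)
    is_coupled[coupled_idx] = True
    coupling_sign = np.zeros(cfg.n_genes)
    n_neg = int(round(cfg.coupled_negative_fraction * cfg.n_coupled))
    signs = np.concatenate([-np.ones(n_neg), np.ones(cfg.n_coupled - n_neg)])
    coupling_sign[coupled_idx] = rng.permutation(signs)

    n_deleted = int(round(cfg.deleted_fraction * cfg.n_genes))
    deletable = np.flatnonzero(~is_coupled)
    deleted_idx = rng.choice(deletable, size=min(n_deleted, deletable.size), replace=False)
    is_deleted = np.zeros(cfg.n_genes, dtype=bool)
    is_deleted[deleted_idx] = True

    n_response = int(round(cfg.response_fraction * cfg.n_genes))
    resp_pool = np.flatnonzero(~is_coupled)
    response_idx = rng.choice(resp_pool, size=min(n_response, resp_pool.size), replace=False)
    response_effect = np.zeros(cfg.n_genes)
    response_effect[response_idx] = rng.normal(0.0, cfg.response_sd, size=response_idx.size)

    # --- conditions and per-condition exponents ---
    conds = _make_conditions(cfg, rng)
    r_cond = {}
    for c in conds:
        r_cond[c["condition_id"]] = max(
            1.05, cfg.r_for(c["genome_class"]) + rng.normal(0.0, cfg.r_sd)
        )

    in_stratum = {}
    for c in conds:
        if cfg.coupled_stratum == "reduced":
            in_stratum[c["condition_id"]] = c["genome_class"] is GenomeClass.REDUCED
        else:  # steady_full
            in_stratum[c["condition_id"]] = (
                c["genome_class"] is GenomeClass.FULL_LENGTH
                and c["state"] is CellState.STEADY
            )
    stratum_rates = [c["growth_rate"] for c in conds if in_stratum[c["condition_id"]]]
    mu_center = float(np.mean(stratum_rates)) if stratum_rates else 0.0

    # --- condition-level expression ---
    # Scores (reference-scale log expression plus noise, coupling and
    # response terms) determine gene ranks; the realized values are the
    # condition's own exact power-law quantiles assigned by rank.  Every
    # condition's marginal therefore follows K^(-r_cond) exactly while
    # cross-condition correlation structure lives in the rank dynamics.
    r_ref = float(
        np.mean(
            [cfg.r_for(GenomeClass.FULL_LENGTH), cfg.r_for(GenomeClass.REDUCED)]
        )
    )
    z = cfg.k_min_log10 - np.log10(u) / r_ref
    cond_expr = {}
    for c in conds:
        cid = c["condition_id"]
        score = z + rng.normal(0.0, cfg.condition_sd, size=cfg.n_genes)
        if in_stratum[cid]:
            # coupling acts on the rank scores, centred so coupled genes
            # keep their baseline rank on average; realized log-expression
            # shifts are the induced quantile displacements, so the
            # marginal stays an exact power law
            score = score + coupling_sign * cfg.coupling_slope * (
                c["growth_rate"] - mu_center
            )
        if c["state"] is CellState.UNSTEADY:
            w = 1.0 if c["zero_growth"] else 0.5
            score = score + w * response_effect
        if c["genome_class"] is GenomeClass.REDUCED:
            pidx = np.flatnonzero(~is_deleted)
        else:
            pidx = np.arange(cfg.n_genes)
        vals_desc = cfg.k_min_log10 - np.log10(np.sort(u[pidx])) / r_cond[cid]
        x = np.full(cfg.n_genes, np.nan)
        order = pidx[np.argsort(-score[pidx], kind="stable")]
        x[order] = vals_desc
        cond_expr[cid] = x

    # --- replicates and detection p-values ---
    columns, col_values, col_pvals = [], [], []
    conditions_out = []
    for c in conds:
        cid = c["condition_id"]
        n_rep = int(rng.integers(cfg.n_replicates[0], cfg.n_replicates[1] + 1))
        rep_ids = []
        for j in range(n_rep):
            did = f"{cid}_r{j + 1}"
            rep_ids.append(did)
            vals = cond_expr[cid] + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            p = np.where(
                is_dropout,
                rng.uniform(0.05, 1.0, size=cfg.n_genes),
                rng.uniform(0.0, 0.04, size=cfg.n_genes),
            )
            missing = ~np.isfinite(cond_expr[cid])
            vals = np.where(missing, np.nan, vals)
            p = np.where(missing, np.nan, p)
            columns.append(did)
            col_values.append(vals)
            col_pvals.append(p)
        conditions_out.append(
            Condition(
                condition_id=cid,
                genome_class=c["genome_class"],
                state=c["state"],
                growth_rate=c["growth_rate"],
                replicate_dataset_ids=tuple(rep_ids),
            )
        )
    values = pd.DataFrame(
        np.column_stack(col_values), index=gene_ids, columns=columns
    )
    values.index.name = "gene_id"
    pvals = pd.DataFrame(np.column_stack(col_pvals), index=gene_ids, columns=columns)
    pvals.index.name = "gene_id"
    expression = ExpressionMatrix(values, pvals)
    condition_table = ConditionTable(conditions_out)

    # --- annotation: categories with planted enrichment of coupled genes ---
    cats = np.array(CATEGORY_NAMES[: cfg.n_categories])
    category = cats[rng.integers(0, cfg.n_categories, size=cfg.n_genes)]
    planted_cat = rng.random(cfg.n_genes) < cfg.coupled_category_prob
    category = np.where(is_coupled & planted_cat, cfg.coupled_category, category)
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"category": category, "in_reduced": ~is_deleted}, index=gene_ids
        )
    )

    # --- regulatory networks ---
    # planted regulons are sign-coherent: a regulon whose members couple in
    # opposite directions would have a flat mean expression
    networks: list[RegulatoryNetwork] = []
    pos_pool = [i for i in coupled_idx if coupling_sign[i] > 0]
    neg_pool = [i for i in coupled_idx if coupling_sign[i] < 0]
    rng.shuffle(pos_pool)
    rng.shuffle(neg_pool)
    cursors = {1: 0, -1: 0}
    pools = {1: pos_pool, -1: neg_pool}
    for k in range(cfg.n_coupled_networks):
        sign = 1 if k % 2 == 0 else -1
        size = int(rng.integers(cfg.coupled_regulon_size[0], cfg.coupled_regulon_size[1] + 1))
        members = pools[sign][cursors[sign] : cursors[sign] + size]
        cursors[sign] += size
        networks.append(
            RegulatoryNetwork(f"tfC{k + 1:02d}", frozenset(gene_ids[members]))
        )
    null_pool = np.flatnonzero(~is_coupled & ~is_dropout)
    for k in range(cfg.n_networks - cfg.n_coupled_networks):
        size = int(
            rng.integers(cfg.regulatees_per_network[0], cfg.regulatees_per_network[1] + 1)
        )
        members = rng.choice(null_pool, size=min(size, null_pool.size), replace=False)
        networks.append(
            RegulatoryNetwork(f"tfN{k + 1:02d}", frozenset(gene_ids[members]))
        )

    truth = StudyTruth(
        coupled_genes=tuple(sorted(gene_ids[coupled_idx])),
        deleted_genes=tuple(sorted(gene_ids[deleted_idx])),
        dropout_genes=tuple(sorted(gene_ids[dropout_idx])),
        response_genes=tuple(sorted(gene_ids[response_idx])),
        coupled_tfs=tuple(f"tfC{k + 1:02d}" for k in range(cfg.n_coupled_networks)),
        r_by_condition=r_cond,
        condition_profiles=pd.DataFrame(
            cond_expr, index=gene_ids, columns=[c["condition_id"] for c in conds]
        ),
    )
    return SyntheticStudy(expression, condition_table, annotation, networks, truth, cfg)
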
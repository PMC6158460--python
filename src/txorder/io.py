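"""Readers and writers for the five flat-file kinds the pipeline touches.

All files are tab-separated UTF-8 with optional ``#``-prefixed comment lines,
matching RegulonDB flat-file and common expression-matrix practice.  Missing
values are the literal ``NA`` on disk and NaN in memory; parsers never coerce
a missing cell to a number.  Gene identifiers are opaque strings (JW numbers
such as ``JW0629`` in the source data) — no identifier mapping is performed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

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

PathLike = Union[str, Path]

_NA = "NA"


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        na_values=[_NA],
        keep_default_na=False,
        **kwargs,
    )


def read_expression_matrix(
    path: PathLike, p_value_path: Optional[PathLike] = None
) -> ExpressionMatrix:
    """Read a genes x data sets matrix (first column gene_id, header of dataset ids).

    Raises on duplicate gene or dataset identifiers and on any shape or
    labelling mismatch between the value matrix and the detection-p matrix.
    """
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    genes = raw[gene_col].tolist()
    dups = sorted({g for g in genes if genes.count(g) > 1})
    if dups:
        raise ValueError(f"duplicate gene_id in {path}: {dups[0]!r}")
    cols = list(raw.columns[1:])
    dup_cols = sorted({c for c in cols if cols.count(c) > 1})
    if dup_cols:
        raise ValueError(f"duplicate dataset_id in {path}: {dup_cols[0]!r}")
    values = raw.set_index(gene_col)[cols].astype(float)
    values.index.name = "gene_id"
    detection = None
    if p_value_path is not None:
        p_raw = _read_tsv(p_value_path)
        detection = p_raw.set_index(p_raw.columns[0]).astype(float)
        detection.index.name = "gene_id"
        if detection.shape != values.shape:
            raise ValueError(
                f"p-value matrix shape {detection.shape} does not match "
                f"expression shape {values.shape}"
            )
        if list(detection.index) != list(values.index) or list(
            detection.columns
        ) != list(values.columns):
            raise ValueError("p-value matrix ids do not match expression matrix ids")
    return ExpressionMatrix(values, detection)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: PathLike, p_value_path: Optional[PathLike] = None
) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep=_NA, index_label="gene_id")
    if p_value_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix carries no detection p-values to write")
        matrix.detection_p.to_csv(p_value_path, sep="\t", na_rep=_NA, index_label="gene_id")


def read_condition_table(path: PathLike) -> ConditionTable:
    """Read condition metadata (replicate dataset ids semicolon-joined)."""
    raw = _read_tsv(path)
    required = ["condition_id", "genome_class", "state", "growth_rate", "dataset_ids"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"condition table {path} missing columns: {missing}")
    conditions = []
    for _, row in raw.iterrows():
        conditions.append(
            Condition(
                condition_id=str(row["condition_id"]),
                genome_class=GenomeClass(row["genome_class"]),
                state=CellState(row["state"]),
                growth_rate=float(row["growth_rate"]),
                replicate_dataset_ids=tuple(
                    d for d in str(row["dataset_ids"]).split(";") if d
                ),
            )
        )
    return ConditionTable(conditions)


def write_condition_table(table: ConditionTable, path: PathLike) -> None:
    rows = [
        {
            "condition_id": c.condition_id,
            "genome_class": c.genome_class.value,
            "state": c.state.value,
            "growth_rate": repr(c.growth_rate),
            "dataset_ids": ";".join(c.replicate_dataset_ids),
        }
        for c in table
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path: PathLike) -> GeneAnnotation:
    raw = _read_tsv(path)
    required = ["gene_id", "category", "in_reduced"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"annotation {path} missing columns: {missing}")
    genes = raw["gene_id"].tolist()
    dups = sorted({g for g in genes if genes.count(g) > 1})
    if dups:
        raise ValueError(f"duplicate annotated gene_id in {path}: {dups[0]!r}")
    tbl = raw.set_index("gene_id")[["category", "in_reduced"]].copy()
    tbl["in_reduced"] = tbl["in_reduced"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if tbl["in_reduced"].isna().any():
        bad = tbl.index[tbl["in_reduced"].isna()][0]
        raise ValueError(f"annotation {path}: unparseable in_reduced for {bad!r}")
    return GeneAnnotation(tbl)


def write_annotation(annotation: GeneAnnotation, path: PathLike) -> None:
    out = annotation.table.copy()
    out["in_reduced"] = out["in_reduced"].map({True: "True", False: "False"})
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_network_file(path: PathLike) -> list[RegulatoryNetwork]:
    """Parse a two-column TF -> regulated-gene flat file (RegulonDB dialect).

    Comment lines start with ``#``; fields are tab-separated; duplicate edges
    collapse to one regulatee.  Returns one network per distinct TF, in order
    of first appearance.
    """
    edges: dict[str, list[str]] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            tf, gene = parts[0].strip(), parts[1].strip()
            if not tf or not gene:
                raise ValueError(f"{path}: empty field in line {line!r}")
            edges.setdefault(tf, [])
            if gene not in edges[tf]:
                edges[tf].append(gene)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"{path}: no edges after comment stripping")
    return [RegulatoryNetwork(tf, frozenset(genes)) for tf, genes in edges.items()]


def write_network_file(networks: Sequence[RegulatoryNetwork], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# tf_id\tgene_id\n")
        for net in networks:
            for g in sorted(net.regulatee_ids):
                fh.write(f"{net.tf_id}\t{g}\n")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
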
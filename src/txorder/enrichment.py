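"""Binomial over-representation of gene selections across functional categories.

A selection of n genes drawn from a genome of G annotated genes is tested
category by category: with g genes of the category in the genome, the number
m landing in the selection is referred to Binomial(n, g/G) and the one-sided
(upper tail) exact p-value P(X >= m) is reported.  Categories smaller than
the size floor (more than 15 genes, i.e. >= 16) are excluded.  No
multiple-testing correction is applied; the deliverable is the raw p grid
with its -log10 transform.  A hypergeometric variant is available behind a
flag for comparison.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .datamodel import EnrichmentResult, GeneAnnotation, ImprovedGene

MIN_CATEGORY_SIZE = 15  # "more than 15": categories of size >= 16 are used

DIRECTIONS = ("reverse", "same", "both")


def binomial_enrichment(
    selected: Iterable[str],
    annotation: GeneAnnotation,
    min_category_size: int = MIN_CATEGORY_SIZE,
    background: Optional[Iterable[str]] = None,
    test: str = "binomial",
) -> list[EnrichmentResult]:
    """Exact one-sided enrichment of ``selected`` genes in each category.

    ``background`` restricts the annotated universe (e.g. to the genes that
    survived the detection filter, or to the reduced-genome annotation);
    selected genes outside the background are ignored.  ``test`` is
    ``"binomial"`` (default) or ``"hypergeometric"``.
    """
    table = annotation.table
    if background is not None:
        bg = [g for g in table.index if g in set(background)]
        table = table.loc[bg]
    G = len(table)
    if G == 0:
        raise ValueError("empty annotation background")
    sel = set(selected) & set(table.index)
    n = len(sel)
    if n == 0:
        raise ValueError("empty gene selection (no selected gene is annotated)")
    cat_sizes = table["category"].value_counts()
    sel_cats = table.loc[sorted(sel), "category"].value_counts()
    results = []
    for cat, g in sorted(cat_sizes.items()):
        if g <= min_category_size:
            continue
        m = int(sel_cats.get(cat, 0))
        if test == "binomial":
            p = float(stats.binom.sf(m - 1, n, g / G)) if m > 0 else 1.0
        elif test == "hypergeometric":
            p = float(stats.hypergeom.sf(m - 1, G, int(g), n)) if m > 0 else 1.0
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(
            EnrichmentResult(
                category=str(cat),
                n_selected_in_category=m,
                n_selected=n,
                category_size=int(g),
                genome_size=G,
                p_value=min(p, 1.0),
            )
        )
    return results


def enrichment_by_direction(
    improved: Sequence[ImprovedGene],
    annotation: GeneAnnotation,
    min_category_size: int = MIN_CATEGORY_SIZE,
    background: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Category x direction grid of enrichment p-values for an improved-gene set.

    Columns are ``reverse`` (sign-flipping genes only), ``same``
    (sign-keeping only) and ``both`` (their union).  An empty direction
    subset yields a column of p = 1 with a flag.  Also carries the per-cell
    selected-in-category counts and -log10 p.
    """
    selections = {
        "reverse": [g.gene_id for g in improved if g.direction == "reverse"],
        "same": [g.gene_id for g in improved if g.direction == "same"],
        "both": [g.gene_id for g in improved],
    }
    frames = []
    for direction in DIRECTIONS:
        sel = selections[direction]
        if not sel:
            # emit the column with p = 1 for every eligible category
            ref = binomial_enrichment(
                list(annotation.gene_ids), annotation, min_category_size, background
            )
            rows = [
                {
                    "category": r.category,
                    "direction": direction,
                    "m": 0,
                    "n_selected": 0,
                    "category_size": r.category_size,
                    "p_value": 1.0,
                    "neg_log10_p": 0.0,
                    "flag": "empty_selection",
                }
                for r in ref
            ]
        else:
            rows = [
                {
                    "category": r.category,
                    "direction": direction,
                    "m": r.n_selected_in_category,
                    "n_selected": r.n_selected,
                    "category_size": r.category_size,
                    "p_value": r.p_value,
                    "neg_log10_p": r.neg_log10_p,
                    "flag": "",
                }
                for r in binomial_enrichment(sel, annotation, min_category_size, background)
            ]
        frames.append(pd.DataFrame(rows))
    grid = pd.concat(frames, ignore_index=True)
    return grid.set_index(["category", "direction"]).sort_index()
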
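# txorder

Multi-level analysis of transcriptome *order*: how genome reduction and the
cellular state reorganize bacterial gene expression, quantified at the
genome-wide, single-gene and regulatory-network levels.

`txorder` is aimed at microbial systems biologists working with
growth-profiled expression compendia — collections of (micro)array or
RNA-seq data sets in which every condition carries a measured specific
growth rate and metadata such as genome class (full-length wild type vs.
engineered reduced genome, e.g. *E. coli* MG1655/DH1 vs. MDS42) and
cellular state (steady exponential growth vs. responsive/unsteady states,
the latter assigned growth rate zero while growth is paused).

## What it computes

**Genome-wide: the Zipf exponent of expression.** For each condition the
cumulative probability that a gene is expressed at level at least *K*
decays approximately as a power law,

    P>(K) ~ K^(-r),

and the exponent *r* is estimated by regression of log₁₀ P>(K) on log₁₀ K
over a fixed window (default log₁₀ K ∈ [−1, 2]). Exponents are compared
between genome classes and cellular states (Welch *t*, with a permutation
cross-check) and correlated against growth rate.

**Single-gene: growth-correlated expression.** Each gene's log₁₀ expression
is Pearson-correlated with growth rate over a condition subset; two-sided
p-values come from t = c·√((n−2)/(1−c²)) with n−2 degrees of freedom.
*Improved-correlation genes* are those with no correlation in a reference
subset (p > 0.01) but a highly significant one in a focal subset
(p < 0.001), classified by whether the coefficient kept (`same`) or flipped
(`reverse`) its sign. Coefficient histograms use 0.1-wide bins on [−1, 1].

**Gene categories: binomial enrichment.** Improved-gene selections are
tested for over-representation in ~20 functional categories (exact binomial
upper tail, categories with more than 15 genes), split by direction
(reverse / same / both).

**Regulons: network-level correlation.** A regulator's network expression is
the unweighted mean log₁₀ expression of its regulatees (RegulonDB-style
TF→gene edge lists); networks with more than 15 regulatees present in the
genome under study are correlated with growth rate, histogrammed (0.2 bins)
and tabulated at p < 0.05.

A synthetic-study generator (`txorder.synthetic_data`) produces complete
compendia with this exact statistical structure — power-law marginals,
planted growth-coupled genes and regulons, biological replicates, detection
p-values, genome reduction as gene deletion — so every stage is testable
against known ground truth. See `docs/methods.md` for the model and design
choices.

## Worked example

```python
from txorder import SimulationConfig, simulate_study
from txorder.pipeline import run_full_analysis

study = simulate_study(SimulationConfig(seed=1))
res = run_full_analysis(study.expression, study.conditions,
                        study.annotation, study.networks)
s = res.summary()
```

Printing the summary fields gives:

```
conditions analysed : 56
genes detected      : 2880 (full-length) / 2245 (reduced)
exponent r range    : 2.23 - 2.67
mean r by genome    : full 2.33, reduced 2.59 (Welch p = 1.3e-10)
r vs growth rate    : p = 0.12
improved genes      : 149 (83 same / 66 reverse direction)
top enriched class  : Enzyme (p = 7.0e-59)
significant regulons: 5 in the reduced subset
```

Reading: all 56 condition-level exponents fall in the 2.2–2.8 band; genome
reduction shifts the mean exponent upward (a *more ordered*, less spread
expression distribution) while the exponent is independent of growth rate;
149 genes gain a strong growth correlation specifically in the
reduced-genome subset (the generator planted 150, with the Enzyme category
enriched by construction); and exactly the five planted regulons reach
significance at the network level.

## Command line

```sh
txorder simulate --config sim.yaml --out bundle/      # synthetic bundle
txorder run-all  --config run.yaml                    # whole pipeline
txorder preprocess|powerlaw|correlate|enrich|networks # single stages
txorder run-all  --config run.yaml --exclude-zero-growth   # sensitivity variant
```

`run-all` takes a YAML config naming either the five input files
(`expression.tsv`, `detection_p.tsv`, `conditions.tsv`, `annotation.tsv`,
`network.tsv` — tab-separated, `#` comments, `NA` for missing) or a
`simulate:` block, plus optional `params:` overrides for every threshold.
Results are TSV/JSON in the output directory; logs go to stderr.

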
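# Methods

This note documents the statistical model behind `txorder`, the defaults
and why they were chosen, the design of the synthetic-study generator, and
the limits of what the test suite can demonstrate.

## Pipeline model

The pipeline assumes gene-level **log₁₀ expression** ("mRNA concentration")
matrices with per-measurement **detection p-values**, grouped into
conditions by a metadata table (genome class, cellular state, specific
growth rate in h⁻¹, replicate membership). Stages, in order:

1. **Detection filter.** A gene is retained for a genome class when *any*
   measurement in that class's arrays has detection p < α (default 0.05).
   Filtering is per genome class because a gene deleted from the reduced
   genome has no measurements there at all; it stays in the full-length
   analyses. Surviving values are never altered, only row membership.
2. **Global normalization.** Each array is shifted additively in log space
   to a common mean (default: the grand mean of the pre-normalization
   column means). An additive log shift is the minimal transform producing
   a "common mean value (logarithmic)" and corresponds to multiplicative
   rescaling of raw concentrations. No quantile or batch correction is
   applied — deliberately out of scope.
3. **Replicate averaging.** Condition profiles are arithmetic means of
   replicate columns in log scale (geometric means of raw concentrations),
   ignoring missing entries.
4. **Condition clustering.** Agglomerative clustering of condition profiles
   on Euclidean distances, furthest-neighbour (complete) linkage by default
   (average and Ward available), restricted to genes with no missing value
   in any condition so all distances use identical coordinates. Output is a
   dendrogram serializable to Newick.

### Power-law (Zipf) exponent

For one condition's expression vector the empirical cumulative probability
is computed at every distinct observed level with the weak inequality,
P>(K) = #{x ≥ K}/n, so the smallest observation has P> = 1 exactly and no
zero enters the logarithm. The exponent *r* is minus the slope of an
ordinary least-squares regression of log₁₀ P> on log₁₀ K restricted to a
window, default log₁₀ K ∈ [−1, 2]. The regression points are the
distinct-value curve points, unweighted; whether one should instead bin
the curve is genuinely open, and the distinct-value choice is the simplest
faithful one. A variance-stabilized alternative (`method="wls_anchored"`,
regression through the window's lower-edge point with weights P/(1−P),
the inverse delta-method sampling variance of log P>) approaches the
information bound r/√n on clean power-law samples, but it leans on the
low-K corner of the curve and is therefore sensitive to measurement noise
there; the robust plain OLS is the default.

Group comparisons of fitted exponents use Welch's two-sample *t*-test
(significance threshold 0.05), with an exhaustive/Monte-Carlo permutation
test provided as a cross-check. Two groups with identical slope multisets
report p = 1 by convention rather than a 0/0 statistic.

### Growth correlations and the improved-gene screen

All correlations are Pearson on (log₁₀ expression, growth rate); a
Spearman option (Pearson on midranks) exists but plays no role in the
defaults. The p-value is the
exact t-transform, t = c·√((n−2)/(1−c²)) with n−2 df, two-sided. Degenerate
cases are flagged rather than coerced: fewer than 3 paired values
(`n_too_small`), zero variance (`zero_variance`), |c| = 1 to machine
precision (`perfect_correlation`, coefficient reported, p undefined).
Flagged genes are excluded from histograms and screens.

The improved-gene screen selects genes with p > 0.01 in the reference
subset and p < 0.001 in the focal subset (both strict, both configurable);
no multiple-testing correction is applied, matching the raw dual-threshold
convention of the analysis this package implements. Direction is `same`
when the coefficient keeps its sign (a strengthening negative correlation
is `same`), `reverse` when it flips; an exactly zero reference coefficient
carries no sign and takes the focal sign.

### Enrichment

One-sided exact binomial: with G annotated background genes, g in the
category, n selected and m selected-in-category, p = P(X ≥ m),
X ~ Binomial(n, g/G), computed via the regularized survival function
(equal to direct tail summation to < 1e−12). The background defaults to
the detection-filtered, annotated gene set of the relevant genome.
Categories with more than 15 genes (≥ 16) are eligible. A hypergeometric
variant is available for comparison but is not the default. The
deliverable is the p and −log₁₀ p grid over categories × direction
(reverse / same / both).

### Regulons

Network expression is the unweighted mean of regulatee log₁₀ expression
(regulatory sign and strength ignored; the TF's own gene counts only if it
appears as a regulatee in the edge list, which is taken literally).
Networks are restricted to the genome under study and kept when more than
15 regulatees remain — so a network can pass in the full-length genome and
fail after genome reduction. Per subset: Pearson correlation of the mean
vector with growth rate, a 0.2-bin coefficient histogram, and a p < 0.05
significance table with −log₁₀ p.

## Synthetic-study generator

The generator emulates a growth-profiled microarray compendium: 56
conditions (44 full-length of which 23 steady; 12 reduced of which 11
steady), 2–7 biological replicates each (~250 arrays), 16 zero-growth
unsteady conditions, ~20 % of genes deleted by genome reduction, 20
functional categories, 40 regulons, 150 planted growth-coupled genes of
which 5 sign-coherent regulons are built.

**Sampling is stratified.** Power-law draws use Latin-hypercube uniforms
(one jittered draw per 1/n stratum, shuffled), so each value is marginally
Pareto while the realized cumulative curve tracks K^(−r) closely at finite
n — the planted exponent is genuinely true of the generated sample, which
is what makes r_true a usable oracle for slope-recovery tests. Growth
rates are likewise stratified over their range, reflecting that a
compendium's conditions are chosen to span slow to fast growth.

**Condition profiles are rank-remapped quantiles.** Each gene carries a
fixed quantile u (shared across conditions). A condition's value set is the
exact Pareto quantile set at its own exponent (class exponent ± per-
condition jitter, reduced-genome conditions using only non-deleted genes);
values are assigned to genes by the rank of a latent score = baseline +
condition-level Gaussian noise + coupling + response terms. Consequences:
every condition's **full marginal is exactly power-law**, and column means
are condition-invariant, so the planted signal cannot leak through global
normalization. The alternative — additive signals on raw log values —
blurs the distribution's lower corner and fattens its sparse tail, biasing
any cumulative-curve regression by several tenths, which is why it was
rejected.

**Coupling.** Planted genes receive a score shift of
`coupling_slope × (μ − μ̄)` inside the declared stratum (default: all
reduced-genome conditions). Signs are exactly balanced (half positive,
half negative): a one-sided planted signal would, by rank conservation /
mean normalization (compositional closure), induce a compensating opposite
trend in *every* background gene — a real phenomenon in global-normalized
expression data, but one that would make the background non-null by
construction. Coupled genes are drawn from the upper 60 % of the baseline
distribution, because a gene at the power-law floor has no downward
dynamic range (the analogue of a detection floor). The realized per-gene
Pearson coefficient in the 12-condition focal subset is ≈ 0.9 — the
strongly-coupled regime the screen is designed to detect. Planted regulons
are disjoint, sign-coherent subsets of the coupled genes.

**Other structure.** A response signature (per-gene N(0, 0.3) shift for a
random 10 % of genes) is applied to unsteady conditions at full strength
when growth is paused and half strength otherwise, so steady-vs-unsteady
contrasts and the clustering are non-trivial. Dropout genes (4 %) have
detection p uniform above the 0.05 cutoff in every array and are removed
by the filter; expressed genes have p uniform on (0, 0.04). Replicates add
N(0, 0.1) log₁₀ noise; condition-level biological variation is N(0, 0.15)
in score space. Coupled genes are biased into one category ("Enzyme",
probability 0.5) so the enrichment stage has a planted answer.

Key defaults (all in `SimulationConfig`, all log₁₀ units unless noted):

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 3000 | order of a bacterial genome after detection filtering |
| `r_true` | (2.4, 2.7) | inside the observed 2.2–2.8 band; reduced genome steeper |
| `r_sd` | 0.05 | spreads condition exponents across the band |
| `k_min_log10` | −1 | lower cutoff; fit window starts here |
| `coupling_slope` | 1.5 per h⁻¹ | realized \|Pearson\| ≈ 0.9 in a 12-condition subset |
| `condition_sd` | 0.15 | condition-to-condition biological variation |
| `noise_sd` | 0.10 | replicate (technical + biological) noise |
| `deleted_fraction` | 0.22 | full-length → reduced gene-count ratio ≈ 0.77 |
| `growth_rate_range` | 0.1–1.5 h⁻¹ | typical *E. coli* range across media/temperatures |
| `zero_growth_fraction` | 16/22 | paused-growth share of unsteady conditions |

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level microarray noise (dye/scanner
effects, probe saturation), operon and chromosomal-position correlation
structure, regulatory sign, condition-specific regulation beyond the
single planted stratum and response signature, and cross-gene dependence
beyond rank competition. Real compendia also have sign-imbalanced
growth-coupled programs (e.g. the ribosomal growth law), which *do* leak
through global normalization; the generator balances signs deliberately,
and users analysing real data should expect mild compositional
anticorrelation in the background.

One structural consequence of the rank design: inside the coupled stratum
at extreme growth rates the planted genes occupy the extreme quantiles, so
the *uncoupled complement* there is tail-truncated and does not itself
pass slope recovery — the full marginal does, exactly. The tests assert
the full marginal everywhere and the uncoupled background outside the
stratum.

## Numerical choices and degenerate inputs

- Missing values are NaN in memory, `NA` on disk; parsers never coerce.
- Ties in the cumulative curve are merged into distinct-level points;
  all-identical vectors are a hard error (no exponent exists).
- Pearson coefficients are clipped to [−1, 1] before the t-transform;
  |c| ≥ 1 − 1e−13 is treated as exact.
- Zero-variance detection in the vectorized per-gene path uses a relative
  tolerance scaled by the data magnitude.
- Histogram bins are left-closed right-open except the last (closed), so
  coefficient 1.0 is counted and totals are conserved.
- Normalization verifies post-shift column means to < 1e−9 log₁₀ units.
- Welch p-values that are non-finite (identical groups) report 1.0.

## Problem sizes in the test suite

Unit tests run on an 800-gene study with the same 56-condition layout as
the default; the end-to-end recovery checks run the full 3000-gene default
study across 50 seeds, exponent recovery uses 2500-gene samples × 60 fits,
and the permutation cross-checks use 10⁵ shuffles. These sizes were chosen
so the whole suite gives stable verdicts in a couple of minutes on one
core.

## Known limitations

- The exact-binomial enrichment is conservative for small categories
  (discreteness); the hypergeometric option is slightly less so but is not
  the analysis default.
- The t-based Pearson p-value is a continuous approximation; for n ≤ 5 the
  exact permutation null has ≤ 120 atoms and the two can differ by more
  than Monte-Carlo error. Subsets that small never occur in the intended
  analyses (the smallest real subset has 12 conditions).
- At the null, ~5 % of analysed networks reach p < 0.05 per subset by
  definition; the significance table is a screen, not a
  multiplicity-corrected inference.
- The slope estimator's accuracy at n ≈ 2500 genes is bounded by the
  information limit r/√n ≈ 0.05; no regression variant can beat it, and
  maximum-likelihood tail fitting is deliberately out of scope.
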
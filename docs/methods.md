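# Methods

## Model and procedure

The pipeline treats candidate-gene prioritization as an overrepresentation
problem. Its core assumption: when a trait maps to several QTL regions, the
causal genes in different regions tend to act in the same biological
process, so the process leaves a detectable footprint across the trait's
combined candidate genes even though each individual region is mostly noise.

Stages, in order:

1. **Region–gene assignment.** A gene belongs to a QTL region when both are
   on the same chromosome and their closed intervals share ≥ 1 base
   (`overlap_rule="any"`; `"contained"` requires the whole gene span inside
   the region). Coordinates are 1-based inclusive internally; BED input is
   converted on read. Strand is stored but never used.
2. **Region size filter.** Regions with more than `max_region_genes` genes
   are excluded *before* anything downstream — including the denominator of
   the region-occurrence fraction. A region with exactly the cutoff count is
   retained. Traits whose every region is excluded are dropped and reported.
3. **Term eligibility.** Terms annotated to at least `max_generality` of the
   genome (strictly: `K/G < max_generality` passes) are removed before
   testing, so very general, uninformative processes never enter the
   multiple-testing burden. The comparator is configurable
   (`generality_cmp="le"`) because "less than 1%" and "not higher than 1%"
   are both defensible readings of the operating point; the strict form is
   the default.
4. **Association testing.** One one-sided Fisher exact test (upper
   hypergeometric tail) per (trait, eligible term observed in the trait's
   candidate set). The background population is the *entire* gene universe
   of the gene-model file, including unannotated genes. BH correction is
   applied once, pooled over all traits and terms. A pair is associated when
   `q ≤ fdr_threshold` **and** the term occurs in at least
   `min_region_fraction` of the trait's retained regions (several annotated
   genes in one region count that region once).
5. **Prioritization.** A candidate gene annotated with ≥ 1 associated term
   is emitted per (trait, region) with its supporting terms. A
   "prime-candidate" refinement lists genes that are their region's *only*
   carrier of a given term.
6. **Validation.** (a) Resampling: per trait, random gene sets of the
   prioritized sizes are drawn without replacement from the candidates;
   the pooled reference overlap over `permutation_iters` iterations gives an
   empirical p. (b) Annotation randomization: whole per-gene term bundles
   are permuted over genes, preserving both marginals of the gene × term
   incidence exactly. (c) GWAS: neighborhoods are the union of the 3 nearest
   genes per SNP. (d) TF profiling: TF percentages in genome, candidates and
   prioritized sets, stratified by the number of traits a gene is
   prioritized for, plus a per-trait TF-family composition table.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `fdr_threshold` | 0.1 | BH q-value cutoff for an association (inclusive ≤). |
| `min_region_fraction` | 0.5 | Term must occur in ≥ half of a trait's retained regions; guards against one gene-dense region driving the signal. |
| `max_generality` | 0.01 | Term annotated to < 1% of the genome; larger terms are unspecific. Strict `<` by default. |
| `max_region_genes` | 450 | Regions with more genes are too poorly resolved to be informative; exactly 450 is retained. |
| `permutation_iters` | 1000 | Resampling-iteration count; the smallest reportable p is then 1/1000, reported as "< 0.001" at a zero count. |
| `alternative` | greater | Enrichment is overrepresentation; a two-sided Fisher variant exists for sensitivity analyses. |
| `include_zero_count_tests` | off | Terms with a = 0 in a trait can never be enriched; testing them only inflates m. Switchable because pooled q-values shift if they are included. |
| `p_estimator` | count | Empirical p = (#null ≥ observed)/n_iter; `plus_one` gives the (c+1)/(n+1) variant. |

The defaults are the method's published operating point, so a bare run is
the canonical analysis.

## The synthetic benchmark

`qtlprio.simulate` generates the study conditions every test runs under:
2 chromosomes × 500 genes (length 1 kb, 1 kb gaps); 50 background BP terms
whose per-term gene counts follow a rank-frequency power law (exponent 1.0)
scaled to ~1 annotation pair per gene and capped at 5% of the genome;
5 traits × 4 QTL regions of 30 consecutive genes placed uniformly; per
region, 2 planted causal genes annotated with a trait-specific causal term
(`f_regions = 1.0`: every region carries signal). These sizes are a
deliberately scaled-down genome with region gene-counts, per-region
term diversity and term-size skew in realistic proportion to crop-genome
inputs (where regions hold ~140 genes of ~39,000 and thousands of BP terms
exist). With the 1% generality threshold the causal terms (8 carriers /
1,000 genes) stay eligible, while the cap keeps the largest background
terms ineligible, so both branches of the eligibility filter are exercised;
setting `f_regions = 0.25` makes the planted term fail the
region-occurrence filter by construction.

Background annotations are positionally independent, so any positional
enrichment is attributable solely to the planting — the generator is a
clean oracle with full ground truth (causal terms, genes, regions; SNPs at
midpoints of planted genes; reference genes as a planted subset). What it
does **not** emulate: linkage/recombination structure, GO-hierarchy
correlations among terms, gene-density and annotation-density
heterogeneity, and trait-name noise. Passing tests therefore demonstrate
correctness of the machinery and sensible statistical behaviour under the
model's own assumptions, not field performance on real compendia.

## Numerical choices

* **Fisher tail** is computed by the exact stable hypergeometric
  survival function (no normal approximation); it matches big-integer
  rational enumeration to < 1e-12 exhaustively for G ≤ 60 (observed
  max |Δ| ≈ 4e-16).
* **BH step-up** is implemented directly (stable mergesort; ties keep input
  order; the running minimum always includes j = m, so outputs are bounded
  by 1 without clipping) and is cross-checked against
  `statsmodels.multipletests(method="fdr_bh")`. Note that pooling *more*
  tests can lower an existing q-value — BH is not monotone in added
  hypotheses — so the suite asserts order-invariance of the pooled
  correction rather than a monotonicity that does not hold.
* **Resampling nulls** draw per-trait hypergeometric variates, which is
  distribution-identical to materializing random gene sets and counting
  reference hits, and makes 1,000-iteration sweeps cheap. All draws are
  `numpy` Generator-based and pure functions of (inputs, seed).
* **SNP–gene distance** is 0 inside a gene span, else the gap to the nearer
  span edge (not the TSS, which the inputs do not provide); ties break by
  (distance, gene_id) for determinism.
* **Uniformity checking** of the resampling p-value is done under a null
  with many traits (50) so the pooled-overlap distribution is smooth; the
  "≥ observed" p-value is discrete, and with few traits its atoms alone
  would exceed a KS bound even for a perfectly calibrated test.
* **Degenerate inputs**: empty SNP files are valid; traits with zero
  retained regions are dropped before the region-fraction denominator could
  be zero; empty eligible-term sets and impossible 2×2 tables raise.

## Design decisions

* Background universe = all genes in the gene-model file, annotated or not;
  restricting to annotated genes is a sensitivity option at input level
  (supply a filtered gene file).
* Generality counts are computed *after* restricting annotations to the
  universe, so K is always consistent with G.
* The observed reference overlap is counted per trait and summed (a gene
  prioritized for two traits can contribute twice), matching the per-trait
  random draws, which are independent across traits within an iteration.
* Trait names are opaque strings; matching traits across datasets is the
  caller's responsibility.
* Annotations are taken as given; no GO ancestor propagation is performed,
  and the pipeline neither knows nor assumes whether the input is
  ancestor-closed.

## Limitations

* Enrichment ignores the GO hierarchy and term–term correlation; closely
  related terms are tested as if independent.
* No use of QTL strength (LOD scores) or interval confidence — every
  retained region weighs equally.
* Selection, not ranking: prioritized genes within a trait are unordered
  (the single-carrier refinement is the only sharper cut).
* Power depends on multiple regions per trait; single-region traits can
  pass the region-occurrence filter trivially (1/1) and rely on the Fisher
  test alone.
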
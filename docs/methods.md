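# Methods

This note documents the models and procedures implemented in `enscnv`,
the parameter choices that matter, what the synthetic generator does
and does not emulate, and the numerical decisions taken where the
design was open.

## Rare/common CNV classification

A case call is compared against a control CNV cohort. A control
*individual* matches when the union of their same-state-class calls on
the same chromosome covers at least `min_overlap` (default 0.75) of
the case call; the call's control frequency is matched individuals
divided by `control_n`, the control cohort size (which may be much
larger than the number of individuals with calls — absence of calls is
informative). The call is rare iff frequency < `freq_cutoff` (default
2.6 × 10⁻⁴, i.e. 0.026%, on the order of Hirschsprung-disease
prevalence). Setting `freq_cutoff ≤ 1/control_n` recovers a strict
"absent from controls" rule.

Decisions:

- **Coordinates** are stored 0-based half-open (BED convention);
  printed clinical tables are 1-based inclusive and converted on input
  (`coordinate_dialect="onebased"`).
- **Overlap is one-way** — the fraction of the *query* covered. This
  is the conservative reading of a "≥ 75% overlap with similar-state
  changes" rule (a small patient deletion inside a large control
  deletion is covered). `reciprocal=True` additionally requires at
  least one single control call to be ≥ 75% covered by the case call.
- **Loss-like states pool** for matching (heterozygous, homozygous and
  X-hemizygous losses form one class); gains match gains only.
- **Union, not sum**: a control individual whose two abutting calls
  tile the query is not double-counted, and classification is
  invariant to splitting control calls into abutting pieces.
- Matching is per *sample*; a sample with several qualifying calls
  counts once in the frequency numerator.

Size z-scores use the sample standard deviation (ddof = 1) over the
rare reference set, optionally stratified by state class.

## Constraint (CCR) rule

A gene is a constrained coding region when

```
(pLI ≥ 0.85) OR (mis_Z ≥ 3) OR (syn_Z ≥ 3)
OR (del_single ≥ 1 AND dup_single ≥ 1 AND cnv_score ≥ 1)
```

AND it is hit at most once by control deletions and at most once by
control duplications. The intolerance clauses are combined with OR
because dosage-score-negative genes with pLI = 1 are bona fide
haploinsufficiency candidates (several of the worked example's genes
have strongly negative CNV dosage scores yet qualify through pLI). A
metric that is unavailable fails only the clause it participates in; a
gene with no metrics at all is "not CCR" and logged. All thresholds
are keyword arguments.

Gene content of a CNV is defined by ≥ 1 bp overlap (half-open
intervals; an abutting gene is not "impacted"): a deletion clipping
any part of a gene can disrupt it, and no overlap fraction for genes
is part of the rule.

## ENS-gene calling

The pipeline on a genes × samples log2 matrix with class labels
(`ENS_GDNF`, `ENS_noGDNF`, `intestine`):

1. **Quantile normalization** of each sample onto the across-sample
   mean order-statistic curve (missing values stay missing; ties get
   the mean of their tied ranks' targets). Normalization runs on the
   **full matrix, before filtering**: it is an array-level
   preprocessing step, and its validity rests on the bulk of measured
   probes being non-differential. Normalizing only the variation
   filter's survivors — which are enriched for truly differential
   genes — measurably absorbs the class difference into the reference
   distribution and destroys the signal.
2. **Filtering**: a gene is kept iff ≥ 20% of its non-missing values
   deviate ≥ log2(1.5) from the gene's median and < 50% of samples are
   missing.
3. **Random-variance model.** Gene precisions are modelled as
   1/σ² ~ Gamma(a, b), under which s²·a·b ~ F(m, 2a) across genes
   (m = residual df). (a, b) are fitted once by maximum likelihood on
   the pooled residual variances of the filtered matrix
   (Nelder–Mead on (log a, log b), moment-based start a₀ = 2,
   b₀ = 1/((a₀−1)·mean s²), tolerance 1e-8 on the log-likelihood).
   Degenerate inputs (all-equal variances, < 2 genes) raise.
4. **Moderated t** per gene and contrast on complete cases within each
   class (n ≥ 2 per class, else the gene is skipped and logged):
   s̃² = (m·s² + 2/b)/(m + 2a), t = (x̄_A − x̄_B)/√(s̃²(1/n_A + 1/n_B)),
   df = m + 2a. In the prior limit a → 0, 1/b → 0 this is exactly the
   pooled two-sample t (verified in the tests).
5. **Permutation p-values**: class labels permuted identically across
   genes. When the number of distinct label assignments is ≤ B all are
   enumerated (p = #{|t*| ≥ |t|}/n_assignments, identity included so
   p > 0); otherwise B Monte-Carlo permutations with the add-one
   estimator p = (1 + #{|t*| ≥ |t|})/(B + 1). Exact permutation ties
   (e.g. the complement assignment) are counted with a 1e-9 tolerance
   so enumeration and Monte-Carlo agree. Default B = 1000.
6. **Calling**: a gene is an ENS gene iff, for **both** contrasts
   (ENS+GDNF vs intestine and ENS−GDNF vs intestine), fold change
   ≥ 1.5 in the ENS direction and permutation p < 0.05. `rule="any"`
   relaxes the conjunction. **No multiple-testing correction is
   applied** — the significance level is nominal per univariate test;
   the conjunction of two contrasts is itself a strong false-positive
   control (≈ α² under the global null).

The comparator class is configurable (one comparator per study; the
container does not distinguish "other intestinal cells" from "total
intestine"). Replicate rows sharing a gene id can be averaged with
`average_replicate_genes` before analysis.

## Risk score

RSnc = Σᵢ ln(ORᵢ) × countᵢ over the risk SNPs in the model, countᵢ the
number of risk alleles (0/1/2). Odds ratios are required input — no
defaults are invented; the synthetic module supplies a field-plausible
set. An OR of 1 contributes exactly 0. Missing genotypes contribute 0
by default; `impute_mean` substitutes the per-SNP cohort mean count
(the Hardy–Weinberg expectation 2p under random mating; the alias
`impute_2pq_mean` is accepted), and `fail` raises.
Haplotype-combination interaction bonuses are deliberately not
modelled. Group summaries use pooled-variance two-tailed t-tests;
groups with fewer than two samples are summarized but excluded from
testing.

## Cohort and zebrafish statistics

- `anova_then_ttests`: one-way ANOVA; pairwise pooled two-tailed
  t-tests run **only** when ANOVA p < 0.05 (Welch available by flag;
  pooled is the default because the source procedure is a Student
  t-test). For two groups F = t² exactly.
- `n1_chisq_2x2`: Pearson χ² (no continuity correction) scaled by
  (N−1)/N, p from χ²₁. Applied to zebrafish data as category I
  (unaffected ENS) vs categories II–V, condition vs control. A zero
  margin raises.
- `neuron_density`: neurons per 100 µm = count/length × 100.
- `dunnett_vs_control`: many-to-one comparisons under equal variances;
  the family-wise adjusted p is Monte-Carlo: group means drawn as
  independent normals with variance 1/nᵢ, a pooled variance drawn as
  χ²_df/df, and pᵢ = P(max_j |T_j| ≥ |tᵢ|) over `n_mc` draws (default
  100,000, seed-reproducible). Monte Carlo was chosen over
  multivariate-t quadrature for transparency and testability; the
  implementation is cross-checked against an independent Dunnett
  implementation in the tests. With one treatment group it reduces to
  the ordinary two-sample p.

## Candidate selection

A (patient, gene) pair is a candidate iff the CNV is rare AND
loss-like AND the gene overlaps it AND is an ENS gene AND a CCR AND
has ≥ 1 zebrafish orthologue (a- and b-duplicates both reported for
targeting). Genes whose ENS status is unevaluable (no mouse orthologue
or no probes; `is_ens_gene is None`) are excluded from candidacy but
reported separately — unevaluable is not negative. Pairs are
deduplicated per (patient, gene) and sorted by patient then genomic
position. The report bundle (per-sample burden, group statistics,
candidate table, JSON summary with thresholds and seed) is
byte-reproducible for identical inputs.

## Synthetic data generator

One global seed feeds fixed per-generator stream ids
(`numpy.random.default_rng([seed, stream])`), so each generator is
reproducible independently of the order in which the others run.
Planted truth (CCR/ENS gene sets, which case CNVs were copied into
controls) is returned alongside the data.

Default study conditions (all configurable in `SimConfig`):

- **Cohort structure**: 3 case groups of 23, 15 and 20 patients and
  326 controls; mean 1.5 CNVs per sample (Poisson); state mix 50%
  loss / 42% gain / 5% homozygous loss / 3% X-hemizygous loss.
- **Sizes**: log10 size ~ N(5.2, 0.3) bp (median ≈ 160 kb), per-group
  and per-state overridable; `planted_loss_size_multiplier` scales
  group-1 losses (1 by default; 10 reproduces the
  "associated-anomalies patients carry larger losses" condition).
  Sizes exceeding the chromosome raise a generation error rather than
  being clipped.
- **Planted common CNVs**: 10% of case calls are copied into one
  control sample with ≤ 5% endpoint jitter, which preserves ≥ 75%
  mutual overlap, so they classify as common against the simulated
  control cohort (denominator 326) while exercising the overlap
  classifier in both directions.
- **Genes**: 2,000 genes of ≤ 20 kb tiled without overlap over a toy
  ~190 Mb genome (4 autosomes + chrX). 20% receive constraint metrics
  passing the CCR rule, the rest failing it; 60% have a mouse
  orthologue, 80% a zebrafish orthologue (30% of those as a/b pairs).
  ENS truth (20% of genes) is planted only among mouse-orthologue
  genes — genes without one are unevaluable on a mouse array — and
  preferentially among CCR genes (P(ENS | CCR) = 0.5), reflecting the
  co-occurrence of constraint and ENS expression in disease genes and
  giving the burden comparison a realistic ENS∧CCR density.
- **Expression**: baseline ~ N(8, 1.5) log2 units; planted ENS genes
  get +log2(fold change) (default fold 4) in both ENS classes; 5
  samples per class; 5% missing completely at random. Noise is
  heteroscedastic across genes — per-gene sd = 0.25 × 10^N(0, 0.35)
  (median 0.25) — and each array carries a global shift (sd 0.2).
  Both are deliberate: with a constant sd the variation filter retains
  almost exclusively the planted genes, and the array shifts are the
  technical effect quantile normalization exists to remove. The
  matrix additionally contains 4,000 non-candidate filler probes,
  because quantile normalization presumes a predominantly
  non-differential probe set, as on a transcriptome-wide array.
- **Genotypes**: Hardy–Weinberg counts Binomial(2, p) at six risk
  SNPs; default frequencies (0.45, 0.35, 0.25, 0.40, 0.10, 0.05) and
  odds ratios (1.8, 1.6, 4.0, 1.4, 1.6, 2.0) — plausible magnitudes
  for the RET, NRG1 and semaphorin risk haplotypes, with the strongest
  weight on the RET enhancer variant. Frequencies exactly 0 or 1 are
  rejected.
- **Phenotypes**: multinomial counts over categories I–V per condition
  (default 60 larvae; control 90% category I, a ret-morpholino
  condition 50%, a crispant condition 65%).

What the generator does **not** emulate: raw probe intensities and
background correction (the matrix is post-summarization log2 scale),
linkage disequilibrium between risk SNPs, sequence-level variants,
genomic CNV hotspots or size/gene-density correlation, and
batch-by-class confounding. Passing recovery tests therefore
demonstrates that the estimators and rules behave correctly under the
generative model's assumptions — not that real array data is free of
artifacts the generator omits.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery studies at
2,000 genes with 1,000 permutations, 5,000 simulated variances for the
RVM fit, 100 random toy genomes for the brute-force oracles, and 50
(tests) or 20 (script) seeded cohort replicates for the burden
enrichment; these sizes give stable Monte-Carlo margins for every
asserted bound while keeping a full run in the tens of seconds.

## Known limitations

- The rarity frequency denominator treats the control cohort as fully
  observed; partially genotyped cohorts would need an effective-n.
- The RVM fit assumes a common residual df m across genes; with
  missing values the per-gene df varies and the modal (complete-case)
  df is used for the fit, while each gene's own m enters its
  moderated t.
- Exhaustive permutation enumerates label assignments, which is exact
  for two-class comparisons but does not extend to paired designs.
- `read_gene_gff3` reads `gene`-type features only; transcript-aware
  (exon-level) intersection is out of scope.
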
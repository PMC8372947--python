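# enscnv

Rare copy-number-variant (CNV) burden analysis and candidate-gene
prioritization for case/control studies of Hirschsprung disease (HSCR)
— the congenital absence of enteric ganglia in the distal colon.

Large CNVs harbour many genes, so pinpointing the culprit within a
deletion is hard. This package implements, as a tested and reusable
Python library, a prioritization strategy built on three signals:

1. **Rarity.** A patient CNV is *rare* when fewer than a cut-off
   fraction (default 0.026%, matched to HSCR prevalence) of control
   individuals carry a same-state copy-number change covering ≥ 75% of
   it. Matching pools loss-like states (heterozygous, homozygous and
   X-hemizygous losses) and counts control *individuals*, not calls.
2. **Constraint (CCR).** A gene is a *constrained coding region* when
   pLI ≥ 0.85, or missense/synonymous Z ≥ 3, or all three
   dosage-sensitivity scores (deletion, duplication, CNV) ≥ 1 — and it
   is not recurrently hit by deletions or duplications in unaffected
   controls.
3. **ENS expression.** An *"ENS gene"* is expressed higher in isolated
   enteric-nervous-system cells (with and without GDNF) than in
   intestine. Calling uses quantile normalization, a
   variation/missingness filter, a two-sample t-test moderated by a
   random-variance model (precisions 1/σ² ~ Γ(a, b), shrunken variance
   s̃² = (m·s² + 2/b)/(m + 2a), df = m + 2a), permutation p-values
   (1,000 permutations, nominal α = 0.05), and a ≥ 1.5 fold-change rule
   required in **both** ENS-vs-intestine contrasts.

Candidates are genes satisfying all of: inside a **rare loss**, **ENS
gene**, **CCR**, and possessing a zebrafish orthologue for in-vivo
follow-up. The package also computes the per-sample non-coding risk
score **RSnc = Σᵢ ln(ORᵢ)·countᵢ** over six HSCR risk-haplotype SNPs,
the cohort group statistics (one-way ANOVA gating pairwise pooled
t-tests), and the zebrafish phenotype statistics ("N-1" chi-squared on
category-I proportions, neuron densities per 100 µm, Monte-Carlo
Dunnett adjustment). A synthetic-data generator emulates every input —
CNV cohorts with planted group-1 loss enlargement, constraint-flagged
genes, ENS-enriched expression, Hardy-Weinberg genotypes, multinomial
phenotype counts — so the full pipeline is testable without patient
data.

## Worked example

`examples/02_candidate_selection_worked_example.py` rebuilds a
published six-patient candidate table and runs the full selection rule:

```
9 candidate (patient, gene) pairs, 9 distinct genes:
AKT3, GABBR1, GNL1, MAPK8, SLC8A1, TBX2, TUBB, UFD1L, USP32

 patient  rsnc   gene                   cnv_region cnv_state  control_frequency
P_000479  4.16 SLC8A1   chr2:40,624,267-40,646,501      loss                0.0
P_000512  8.31   TUBB   chr6:28,005,012-31,683,185      loss                0.0
...
P_002431  9.37   AKT3 chr1:243,963,527-244,016,804      loss                0.0
```

Each row is one (patient, gene) pair whose rare copy-number loss
contains an ENS-expressed, constrained gene with a zebrafish
orthologue; `rsnc` is that patient's non-coding risk score and
`control_frequency` the CNV's frequency in the external control cohort
(0 = absent). The nine distinct genes are the study-level candidate
set.

The other scripts under `examples/` each demonstrate one capability
(rare/common classification, ENS-gene calling with recovery metrics,
risk scores, zebrafish statistics, and the full synthetic cohort with
burden enrichment and report assembly).

## Layout

- `src/enscnv/cnv.py` — CNV data model, TSV/BED I/O, overlap and
  rare/common classification, size z-scores
- `src/enscnv/genes.py` — gene models, constraint (CCR) rule,
  gene-content intersection, per-sample burden profiles
- `src/enscnv/expression.py` — expression study container, filtering,
  quantile normalization, RVM moderated t, permutation p, ENS calling
- `src/enscnv/risk.py` — risk model, RSnc, group comparison
- `src/enscnv/stats.py` — ANOVA-gated t-tests, "N-1" chi-squared,
  neuron densities, Dunnett vs control
- `src/enscnv/prioritize.py` — candidate selection and report bundle
- `src/enscnv/synthetic.py` — the synthetic study generator
- `src/enscnv/workflows.py` — end-to-end orchestration helpers
- `src/enscnv/worked_example.py` — the published six-patient fixture
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations
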
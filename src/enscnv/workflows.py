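"""End-to-end workflows stitching the pipeline stages together.

These are thin orchestration helpers used by the examples, the tests
and the acceptance script; every step is a public function of the
stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cnv import classify_cohort
from .genes import annotate_ccr, ccr_ens_burden
from .stats import AnovaResult, anova_then_ttests
from .synthetic import (
    CnvCohortSim,
    GeneAnnotationSim,
    SimConfig,
    simulate_cnv_cohorts,
    simulate_gene_annotation,
)


@dataclass
class BurdenAnalysis:
    """Per-sample burden profiles plus the group comparisons."""

    burden: pd.DataFrame  # indexed by sample, includes a group column
    anova: dict[str, AnovaResult]  # per burden metric
    cohort: CnvCohortSim
    annotation: GeneAnnotationSim

    def pairwise_p(self, metric: str, group_a: int = 1, group_b: int = 4) -> float:
        """ANOVA-gated pairwise t-test p for one metric (NaN if not run)."""
        res = self.anova[metric]
        if res.pairwise is None:
            return float("nan")
        row = res.pairwise[
            (res.pairwise["group_a"] == group_a) & (res.pairwise["group_b"] == group_b)
        ]
        return float(row["p"].iloc[0]) if len(row) else float("nan")


def run_burden_analysis(
    cfg: SimConfig,
    metrics: tuple[str, ...] = (
        "n_rare_cnvs",
        "total_size",
        "loss_size",
        "ens_genes",
        "ccr_genes",
        "ens_ccr_genes",
        "ens_genes_loss",
        "ccr_genes_loss",
        "ens_ccr_genes_loss",
    ),
    use_planted_ens_truth: bool = True,
) -> BurdenAnalysis:
    """Simulate a cohort and run the rare-CNV burden group comparison.

    Case calls are classified against the simulated control cohort
    (denominator = number of control individuals); control calls are
    classified leave-one-out against the same cohort.  Gene flags come
    from the constraint rule and — by default — from the planted ENS
    truth, so this workflow isolates the CNV-burden question from
    expression-calling noise (set ``use_planted_ens_truth=False`` only
    if you attach ENS flags yourself beforehand).
    """
    cohort = simulate_cnv_cohorts(cfg)
    annotation = simulate_gene_annotation(cfg)
    genes = annotate_ccr(annotation.genes)
    if use_planted_ens_truth:
        for g in genes:
            if g.mouse_orthologue is None:
                g.is_ens_gene = None  # unevaluable on a mouse array
            else:
                g.is_ens_gene = g.symbol in annotation.ens_genes

    case_rarity = classify_cohort(
        cohort.cases, cohort.controls, control_n=cfg.n_controls
    )
    control_rarity = classify_cohort(
        cohort.controls, cohort.controls, control_n=cfg.n_controls, exclude_self=True
    )
    all_samples = [s for grp in cohort.samples_by_group.values() for s in grp]
    group_of = {
        s: g for g, samples in cohort.samples_by_group.items() for s in samples
    }
    burden = ccr_ens_burden(
        case_rarity + control_rarity, genes, samples=all_samples, groups=group_of
    )
    anova = {
        m: anova_then_ttests(
            {g: burden.loc[burden["group"] == g, m] for g in sorted(set(group_of.values()))}
        )
        for m in metrics
    }
    return BurdenAnalysis(burden=burden, anova=anova, cohort=cohort, annotation=annotation)
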
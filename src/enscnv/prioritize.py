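"""Final candidate-gene selection and report assembly.

A (gene, patient) pair becomes a candidate when the patient's CNV is a
rare copy-number LOSS, the gene lies inside it, the gene is an "ENS
gene" (higher expressed in enteric-nervous-system cells than in
intestine), a constrained coding region (CCR), and has at least one
zebrafish orthologue so it can be functionally tested.  Genes whose
ENS status could not be evaluated (no mouse orthologue or no probes)
are excluded from candidacy but reported separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cnv import RarityCall
from .genes import GeneRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    symbol: str
    patient_id: str
    cnv: RarityCall
    is_loss: bool
    is_ens: bool
    is_ccr: bool
    has_zebrafish_orthologue: bool
    patient_rsnc: Optional[float] = None


@dataclass
class PrioritizationResult:
    candidates: list[CandidateGene]
    unevaluable: list[tuple[str, str]]  # (patient, gene) pairs skipped

    def symbols(self) -> list[str]:
        return sorted({c.symbol for c in self.candidates})


def select_candidates(
    rarity_calls: Sequence[RarityCall],
    genes: Sequence[GeneRecord],
    rsnc_by_sample: Optional[Mapping[str, float]] = None,
    require_zebrafish: bool = True,
) -> PrioritizationResult:
    """Emit candidate (gene, patient) pairs from annotated inputs.

    Requires every gene to carry an ``is_ccr`` flag; genes with
    ``is_ens_gene is None`` are unevaluable and collected separately.
    Duplicates from overlapping CNVs in one patient are deduplicated
    per (patient, gene).  Output is sorted by patient, then genomic
    position.
    """
    from .genes import genes_in_cnv

    unflagged = [g.gene_id for g in genes if g.is_ccr is None]
    if unflagged:
        raise ValueError(
            f"genes without is_ccr flag (e.g. {unflagged[0]}); run annotation first"
        )
    seen: set[tuple[str, str]] = set()
    candidates: list[CandidateGene] = []
    unevaluable: list[tuple[str, str]] = []
    for rc in rarity_calls:
        if not (rc.is_rare and rc.call.is_loss_like()):
            continue
        patient = rc.call.sample_id
        for g in genes_in_cnv(rc.call, genes):
            key = (patient, g.gene_id)
            if key in seen:
                continue
            if g.is_ens_gene is None:
                seen.add(key)
                unevaluable.append(key)
                continue
            has_zf = len(g.zebrafish_orthologues) > 0
            if g.is_ens_gene and g.is_ccr and (has_zf or not require_zebrafish):
                seen.add(key)
                candidates.append(
                    CandidateGene(
                        gene_id=g.gene_id,
                        symbol=g.symbol,
                        patient_id=patient,
                        cnv=rc,
                        is_loss=True,
                        is_ens=True,
                        is_ccr=True,
                        has_zebrafish_orthologue=has_zf,
                        patient_rsnc=(
                            rsnc_by_sample.get(patient) if rsnc_by_sample else None
                        ),
                    )
                )
    candidates.sort(
        key=lambda c: (
            c.patient_id,
            c.cnv.call.interval.chrom,
            c.cnv.call.interval.start,
        )
    )
    return PrioritizationResult(candidates=candidates, unevaluable=sorted(unevaluable))


def candidates_table(result: PrioritizationResult) -> pd.DataFrame:
    """Candidate list in a publication-style layout (one row per pair)."""
    rows = []
    for c in result.candidates:
        iv = c.cnv.call.interval
        rows.append(
            {
                "patient": c.patient_id,
                "rsnc": c.patient_rsnc,
                "gene": c.symbol,
                "cnv_region": f"{iv.chrom}:{iv.start + 1:,}-{iv.end:,}",
                "cnv_state": c.cnv.call.state,
                "control_frequency": c.cnv.frequency,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient", "rsnc", "gene", "cnv_region", "cnv_state", "control_frequency"]
    )


def cohort_report(
    out_dir,
    burden: Optional[pd.DataFrame] = None,
    group_stats: Optional[pd.DataFrame] = None,
    prioritization: Optional[PrioritizationResult] = None,
    thresholds: Optional[Mapping[str, object]] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write the report bundle (TSVs + JSON summary) to ``out_dir``.

    Missing stages raise with an explicit list of what is absent.
    Rerunning with identical inputs produces byte-identical files.
    """
    missing = [
        name
        for name, value in (
            ("burden", burden),
            ("group_stats", group_stats),
            ("prioritization", prioritization),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"cohort_report is missing stages: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    burden.to_csv(out / "per_sample_burden.tsv", sep="\t")
    group_stats.to_csv(out / "group_statistics.tsv", sep="\t", index=False)
    cand = candidates_table(prioritization)
    cand.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    summary = {
        "n_samples": int(burden.shape[0]),
        "n_candidates": int(cand.shape[0]),
        "candidate_genes": prioritization.symbols(),
        "n_unevaluable_pairs": len(prioritization.unevaluable),
        "thresholds": dict(thresholds or {}),
        "seed": seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
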
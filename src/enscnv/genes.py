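"""Gene-content annotation of CNVs and the constrained-coding-region rule.

Genes are intervals carrying population-constraint metrics (pLI,
missense/synonymous Z, dosage-sensitivity scores) and orthologue ids
for mouse and zebrafish (which may occur as a/b duplicates after the
teleost genome duplication).  A gene is a *constrained coding region*
(CCR) when it is intolerant to coding variation or to dosage change
and is not recurrently hit by deletions or duplications in unaffected
controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cnv import CnvCall, GenomicInterval, RarityCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConstraintMetrics:
    """Per-gene constraint and dosage-sensitivity metrics.

    ``None`` marks a metric that is unavailable; a missing metric fails
    only the clause it participates in.
    """

    pli: Optional[float] = None
    mis_z: Optional[float] = None
    syn_z: Optional[float] = None
    del_single: Optional[float] = None
    dup_single: Optional[float] = None
    cnv_score: Optional[float] = None
    control_del_events: int = 0
    control_dup_events: int = 0

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI must be in [0, 1], got {self.pli}")


@dataclass
class GeneRecord:
    """A gene interval with annotation flags filled in by pipeline stages."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    mouse_orthologue: Optional[str] = None
    zebrafish_orthologues: list[str] = field(default_factory=list)
    constraint: Optional[ConstraintMetrics] = None
    is_ens_gene: Optional[bool] = None  # None = not evaluable
    is_ccr: Optional[bool] = None


def is_ccr(
    metrics: Optional[ConstraintMetrics],
    pli_min: float = 0.85,
    z_min: float = 3.0,
    dosage_min: float = 1.0,
    max_control_events: int = 1,
) -> bool:
    """Constrained-coding-region rule.

    A gene qualifies when any of: pLI >= ``pli_min``; missense Z >=
    ``z_min``; synonymous Z >= ``z_min``; or all three dosage scores
    (deletion, duplication, CNV) >= ``dosage_min`` — and it is not hit
    more than ``max_control_events`` times by control deletions nor by
    control duplications.  Missing metrics fail their clause; a wholly
    missing metrics record is not a CCR (logged).
    """
    if metrics is None:
        log.debug("constraint metrics missing; gene not considered a CCR")
        return False

    def ge(value: Optional[float], threshold: float) -> bool:
        return value is not None and value >= threshold

    intolerant = (
        ge(metrics.pli, pli_min)
        or ge(metrics.mis_z, z_min)
        or ge(metrics.syn_z, z_min)
        or (
            ge(metrics.del_single, dosage_min)
            and ge(metrics.dup_single, dosage_min)
            and ge(metrics.cnv_score, dosage_min)
        )
    )
    not_recurrent = (
        metrics.control_del_events <= max_control_events
        and metrics.control_dup_events <= max_control_events
    )
    return intolerant and not_recurrent


def annotate_ccr(genes: Iterable[GeneRecord], **thresholds) -> list[GeneRecord]:
    """Set ``is_ccr`` on every gene from its constraint metrics."""
    out = []
    for g in genes:
        g.is_ccr = is_ccr(g.constraint, **thresholds)
        out.append(g)
    return out


def genes_in_cnv(call: CnvCall, genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes overlapping the CNV by >= 1 bp, in genomic order.

    Half-open intervals: a gene abutting the CNV end is excluded.
    """
    hits = [g for g in genes if g.interval.overlaps(call.interval)]
    hits.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
    return hits


# ---------------------------------------------------------------------------
# Per-sample burden profiles

BURDEN_COLUMNS = [
    "n_rare_cnvs",
    "total_size",
    "loss_size",
    "ens_genes",
    "ccr_genes",
    "ens_ccr_genes",
    "ens_genes_loss",
    "ccr_genes_loss",
    "ens_ccr_genes_loss",
]


def ccr_ens_burden(
    rarity_calls: Sequence[RarityCall],
    genes: Sequence[GeneRecord],
    samples: Optional[Sequence[str]] = None,
    groups: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-sample rare-CNV burden profile.

    Counts, per sample: rare CNVs, summed rare-CNV size (all / losses),
    and ENS, CCR and ENS-and-CCR genes inside rare CNVs (all / losses
    only).  A gene hit by two rare CNVs of one sample is counted per
    event.  ``samples`` adds all-zero rows for samples without any rare
    call; ``groups`` attaches a group column.

    All genes must carry ``is_ccr`` and evaluable genes ``is_ens_gene``
    flags; genes with ``is_ens_gene is None`` are unevaluable and never
    counted as ENS.
    """
    unflagged = [g.gene_id for g in genes if g.is_ccr is None]
    if unflagged:
        raise ValueError(
            f"{len(unflagged)} genes lack an is_ccr flag (e.g. {unflagged[0]}); "
            "run annotate_ccr / ENS annotation first"
        )
    rows: dict[str, dict[str, float]] = {}
    if samples is not None:
        for s in samples:
            rows[s] = dict.fromkeys(BURDEN_COLUMNS, 0)
    for rc in rarity_calls:
        if not rc.is_rare:
            continue
        s = rc.call.sample_id
        row = rows.setdefault(s, dict.fromkeys(BURDEN_COLUMNS, 0))
        hit = genes_in_cnv(rc.call, genes)
        n_ens = sum(1 for g in hit if g.is_ens_gene)
        n_ccr = sum(1 for g in hit if g.is_ccr)
        n_both = sum(1 for g in hit if g.is_ens_gene and g.is_ccr)
        row["n_rare_cnvs"] += 1
        row["total_size"] += rc.call.interval.size()
        row["ens_genes"] += n_ens
        row["ccr_genes"] += n_ccr
        row["ens_ccr_genes"] += n_both
        if rc.call.is_loss_like():
            row["loss_size"] += rc.call.interval.size()
            row["ens_genes_loss"] += n_ens
            row["ccr_genes_loss"] += n_ccr
            row["ens_ccr_genes_loss"] += n_both
    df = pd.DataFrame.from_dict(rows, orient="index", columns=BURDEN_COLUMNS)
    df.index.name = "sample"
    df = df.sort_index()
    if groups is not None:
        df.insert(0, "group", [groups.get(s) for s in df.index])
    return df


# ---------------------------------------------------------------------------
# I/O


def read_gene_bed(path) -> list[GeneRecord]:
    """Read gene models from BED (>= 4 columns; name = gene id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for i, row in df.iterrows():
        gene_id = str(row[3]) if len(row) > 3 else f"gene{i}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=gene_id,
                interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
            )
        )
    return genes


def read_gene_gff3(path) -> list[GeneRecord]:
    """Read gene features (type == 'gene') from a GFF3 file.

    GFF3 is 1-based inclusive; converted to half-open. Gene id taken
    from the ID attribute, symbol from Name (falling back to ID).
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"gene{len(genes)}")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    symbol=attrs.get("Name", gene_id),
                    interval=GenomicInterval(parts[0], int(parts[3]) - 1, int(parts[4])),
                )
            )
    return genes


def attach_constraint(genes: Iterable[GeneRecord], path) -> list[GeneRecord]:
    """Join a constraint-metrics TSV (keyed by ``symbol``) onto genes."""
    df = pd.read_csv(path, sep="\t").set_index("symbol")
    num_cols = ["pli", "mis_z", "syn_z", "del_single", "dup_single", "cnv_score"]
    out = []
    for g in genes:
        if g.symbol in df.index:
            row = df.loc[g.symbol]
            kwargs = {
                c: (None if pd.isna(row.get(c)) else float(row[c])) for c in num_cols
            }
            g.constraint = ConstraintMetrics(
                control_del_events=int(row.get("control_del_events", 0) or 0),
                control_dup_events=int(row.get("control_dup_events", 0) or 0),
                **kwargs,
            )
        out.append(g)
    return out


def attach_orthologues(genes: Iterable[GeneRecord], path) -> list[GeneRecord]:
    """Join an orthologue-map TSV (symbol, mouse, zebrafish comma-list)."""
    df = pd.read_csv(path, sep="\t").set_index("symbol")
    out = []
    for g in genes:
        if g.symbol in df.index:
            row = df.loc[g.symbol]
            mouse = row.get("mouse")
            g.mouse_orthologue = None if pd.isna(mouse) else str(mouse)
            zf = row.get("zebrafish")
            g.zebrafish_orthologues = (
                [] if pd.isna(zf) or not str(zf) else str(zf).split(",")
            )
        out.append(g)
    return out
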
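"""Synthetic cohort generator for every input the pipeline consumes.

Emulates the structure of a Hirschsprung-disease CNV case/control
study: three case groups (defaults 23, 15 and 20 patients — an
associated-anomalies group, a known-coding-variant group and an
isolated-disease group) plus 326 unaffected controls; per-group CNV
size distributions with an optional planted size multiplier on group-1
losses; constraint-flagged genes tiled over a toy genome; mouse
ENS-vs-intestine expression with planted higher-expressed "ENS genes";
Hardy-Weinberg genotypes at six risk SNPs; and multinomial zebrafish
phenotype-category counts.

Planted truth (which genes are CCR/ENS, which case CNVs were copied
into controls to become common) is returned alongside the data so
recovery by the downstream classifiers can be measured.

One global seed feeds a fixed per-generator stream id, so each
generator is reproducible independently of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import CnvCall, GenomicInterval
from .genes import ConstraintMetrics, GeneRecord

PHENOTYPE_CATEGORIES = ("I", "II", "III", "IV", "V")

# fixed stream ids so one generator can change without moving the others
_STREAM_CNV = 1
_STREAM_GENES = 2
_STREAM_EXPR = 3
_STREAM_GENO = 4
_STREAM_PHENO = 5

DEFAULT_GENOME = (
    ("chr1", 40_000_000),
    ("chr2", 40_000_000),
    ("chr3", 40_000_000),
    ("chr4", 40_000_000),
    ("chrX", 30_000_000),
)

DEFAULT_PHENOTYPE_PROBS = {
    "control": (0.90, 0.04, 0.03, 0.02, 0.01),
    "ret_mo": (0.50, 0.20, 0.15, 0.10, 0.05),
    "candidate_crispants": (0.65, 0.15, 0.10, 0.06, 0.04),
}


class GenerationError(RuntimeError):
    """Raised when a configuration cannot produce valid data."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with cohort-realistic defaults."""

    seed: int = 0
    n_controls: int = 326
    n_cases_per_group: tuple[int, int, int] = (23, 15, 20)
    control_cnv_rate: float = 1.5  # mean CNVs per sample (Poisson)
    size_log10_mu: float = 5.2  # ~160 kb median CNV
    size_log10_sigma: float = 0.3
    size_params_override: Mapping[tuple[int, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (group, state_class) -> (mu, sigma)
    planted_loss_size_multiplier: float = 1.0  # applied to group-1 losses
    state_probs: tuple[float, float, float, float] = (0.50, 0.42, 0.05, 0.03)
    # order: loss, gain, homozygous_loss, hemizygous_loss (forced to chrX)
    frac_common_cases: float = 0.10  # case CNVs copied into controls
    n_common_copies: int = 1
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_genes: int = 2000
    gene_length: int = 20_000
    frac_ccr: float = 0.20
    frac_ens: float = 0.20
    ens_ccr_overlap: float = 0.50  # P(ENS | CCR-planted gene)
    frac_mouse_orthologue: float = 0.60
    frac_zebrafish_orthologue: float = 0.80
    n_samples_per_class: int = 5
    ens_fold_change: float = 4.0
    expr_noise_sd: float = 0.25  # median per-gene noise sd (log2 scale)
    expr_noise_sd_spread: float = 0.35  # log10-sd of gene-wise sd multipliers
    expr_array_shift_sd: float = 0.20  # per-array global shift, removed by QN
    n_array_filler_genes: int = 4000  # non-candidate transcripts on the array
    frac_missing: float = 0.05
    snp_freqs: tuple[float, ...] = (0.45, 0.35, 0.25, 0.40, 0.10, 0.05)
    snp_ors: tuple[float, ...] = (1.8, 1.6, 4.0, 1.4, 1.6, 2.0)
    phenotype_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_PROBS)
    )
    n_larvae_per_condition: int = 60

    def __post_init__(self) -> None:
        for frac in (
            self.frac_common_cases,
            self.frac_ccr,
            self.frac_ens,
            self.ens_ccr_overlap,
            self.frac_mouse_orthologue,
            self.frac_zebrafish_orthologue,
            self.frac_missing,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if abs(sum(self.state_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.state_probs
        ):
            raise ValueError("state_probs must be non-negative and sum to 1")
        for cond, probs in self.phenotype_probs.items():
            if len(probs) != len(PHENOTYPE_CATEGORIES):
                raise ValueError(f"{cond}: need 5 category probabilities")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{cond}: probabilities must sum to 1")
        if len(self.snp_freqs) != len(self.snp_ors):
            raise ValueError("snp_freqs and snp_ors must have equal length")
        if any(not 0.0 < f < 1.0 for f in self.snp_freqs):
            raise ValueError("allele frequencies must be strictly inside (0, 1)")
        if any(o <= 0 for o in self.snp_ors):
            raise ValueError("odds ratios must be positive")
        if not self.ens_fold_change >= 1.0:
            raise ValueError("ens_fold_change must be >= 1")
        if not self.expr_noise_sd > 0:
            raise ValueError("expr_noise_sd must be > 0")
        if self.planted_loss_size_multiplier <= 0:
            raise ValueError("planted_loss_size_multiplier must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# CNV cohorts


@dataclass
class CnvCohortSim:
    cases: list[CnvCall]
    controls: list[CnvCall]
    samples_by_group: dict[int, list[str]]
    planted_common_case_idx: list[int]  # indices into ``cases``


_STATES = ("loss", "gain", "homozygous_loss", "hemizygous_loss")


def _draw_call(
    cfg: SimConfig, rng: np.random.Generator, sample: str, group: int
) -> CnvCall:
    state = _STATES[rng.choice(4, p=cfg.state_probs)]
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    if state == "hemizygous_loss":
        chrom = "chrX"
        chrom_len = dict(cfg.genome)["chrX"]
    else:
        i = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom, chrom_len = cfg.genome[i]
    state_class = "gain" if state == "gain" else "loss"
    mu, sigma = cfg.size_params_override.get(
        (group, state_class), (cfg.size_log10_mu, cfg.size_log10_sigma)
    )
    size = 10.0 ** rng.normal(mu, sigma)
    if group == 1 and state_class == "loss":
        size *= cfg.planted_loss_size_multiplier
    size = int(round(size))
    if size < 1:
        raise GenerationError(f"drew non-positive CNV size {size}")
    if size > chrom_len:
        raise GenerationError(
            f"CNV size {size} exceeds {chrom} length {chrom_len}; "
            "reduce size parameters or the multiplier"
        )
    start = int(rng.integers(0, chrom_len - size + 1))
    return CnvCall(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, start + size),
        state=state,
        inheritance="unknown",
        group=group,
    )


def simulate_cnv_cohorts(cfg: SimConfig) -> CnvCohortSim:
    """Generate case and control CNV call sets.

    Group-1 loss sizes carry ``planted_loss_size_multiplier``.  A
    fraction ``frac_common_cases`` of case CNVs is copied into
    ``n_common_copies`` control samples with small endpoint jitter
    (within 5% of the size, preserving >= 75% mutual overlap) so that
    they classify as common against the control set.
    """
    rng = cfg.rng(_STREAM_CNV)
    samples_by_group: dict[int, list[str]] = {}
    cases: list[CnvCall] = []
    for g, n in zip((1, 2, 3), cfg.n_cases_per_group):
        samples_by_group[g] = [f"G{g}_{i:04d}" for i in range(n)]
        for s in samples_by_group[g]:
            for _ in range(rng.poisson(cfg.control_cnv_rate)):
                cases.append(_draw_call(cfg, rng, s, g))
    control_samples = [f"C_{i:04d}" for i in range(cfg.n_controls)]
    samples_by_group[4] = control_samples
    controls: list[CnvCall] = []
    for s in control_samples:
        for _ in range(rng.poisson(cfg.control_cnv_rate)):
            controls.append(_draw_call(cfg, rng, s, 4))

    planted: list[int] = []
    if cfg.frac_common_cases > 0 and cases and cfg.n_controls > 0:
        n_plant = int(round(cfg.frac_common_cases * len(cases)))
        idx = rng.choice(len(cases), size=n_plant, replace=False)
        chrom_len = dict(cfg.genome)
        for i in sorted(int(j) for j in idx):
            call = cases[i]
            size = call.interval.size()
            recipients = rng.choice(
                cfg.n_controls, size=min(cfg.n_common_copies, cfg.n_controls), replace=False
            )
            for r in recipients:
                jitter = rng.integers(-size // 20, size // 20 + 1, size=2)
                start = max(0, call.interval.start + int(jitter[0]))
                end = min(chrom_len[call.interval.chrom], call.interval.end + int(jitter[1]))
                controls.append(
                    CnvCall(
                        sample_id=control_samples[int(r)],
                        interval=GenomicInterval(call.interval.chrom, start, end),
                        state=call.state if call.state != "hemizygous_loss" else "loss",
                        inheritance="unknown",
                        group=4,
                    )
                )
            planted.append(i)
    return CnvCohortSim(cases, controls, samples_by_group, planted)


# ---------------------------------------------------------------------------
# Genes, constraint metrics and orthologues


@dataclass
class GeneAnnotationSim:
    genes: list[GeneRecord]
    orthologues: pd.DataFrame  # symbol, mouse, zebrafish
    ccr_genes: set[str]
    ens_genes: set[str]


_CCR_METRICS = ConstraintMetrics(
    pli=0.99, mis_z=4.0, syn_z=0.5, del_single=1.5, dup_single=1.5, cnv_score=1.5
)
_NON_CCR_METRICS = ConstraintMetrics(
    pli=0.10, mis_z=0.5, syn_z=0.2, del_single=-1.0, dup_single=-1.0, cnv_score=-1.0
)


def simulate_gene_annotation(cfg: SimConfig) -> GeneAnnotationSim:
    """Tile non-overlapping genes over the genome and plant annotations.

    ``frac_ccr`` of genes receive constraint metrics passing the CCR
    rule (the rest failing it).  ENS-gene truth is planted only among
    genes with a mouse orthologue (the expression data downstream is a
    mouse array, so genes without one are unevaluable); a CCR-planted
    gene is ENS with probability ``ens_ccr_overlap`` to mimic the
    co-occurrence of constraint and ENS expression in disease genes.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = cfg.rng(_STREAM_GENES)
    total = sum(length for _, length in cfg.genome)
    spacing = total // cfg.n_genes
    gene_len = min(cfg.gene_length, max(1, spacing // 2))
    bounds = np.cumsum([0] + [length for _, length in cfg.genome])

    genes: list[GeneRecord] = []
    for i in range(cfg.n_genes):
        offset = i * spacing + (spacing - gene_len) // 2
        ci = int(np.searchsorted(bounds, offset, side="right") - 1)
        chrom, chrom_len = cfg.genome[ci]
        start = offset - int(bounds[ci])
        end = min(start + gene_len, chrom_len)
        symbol = f"GENE{i:05d}"
        genes.append(
            GeneRecord(gene_id=symbol, symbol=symbol, interval=GenomicInterval(chrom, start, end))
        )

    n = cfg.n_genes
    ccr_idx = set(rng.choice(n, size=int(round(cfg.frac_ccr * n)), replace=False).tolist())
    has_mouse = rng.random(n) < cfg.frac_mouse_orthologue
    has_zf = rng.random(n) < cfg.frac_zebrafish_orthologue

    # ENS planting: prefer CCR genes (w.p. ens_ccr_overlap), restricted to
    # mouse-orthologue genes, topped up from the remaining evaluable genes.
    n_ens_target = int(round(cfg.frac_ens * n))
    evaluable = [i for i in range(n) if has_mouse[i]]
    ens_idx: set[int] = set()
    ccr_evaluable = [i for i in evaluable if i in ccr_idx]
    take = rng.random(len(ccr_evaluable)) < cfg.ens_ccr_overlap
    ens_idx.update(i for i, t in zip(ccr_evaluable, take) if t)
    pool = [i for i in evaluable if i not in ens_idx]
    remaining = max(0, n_ens_target - len(ens_idx))
    if remaining > len(pool):
        remaining = len(pool)
    if remaining:
        ens_idx.update(int(j) for j in rng.choice(pool, size=remaining, replace=False))

    ortho_rows = []
    for i, g in enumerate(genes):
        g.constraint = _CCR_METRICS if i in ccr_idx else _NON_CCR_METRICS
        g.mouse_orthologue = g.symbol.lower().capitalize() if has_mouse[i] else None
        if has_zf[i]:
            base = g.symbol.lower()
            g.zebrafish_orthologues = (
                [base + "a", base + "b"] if rng.random() < 0.3 else [base]
            )
        else:
            g.zebrafish_orthologues = []
        ortho_rows.append(
            {
                "symbol": g.symbol,
                "mouse": g.mouse_orthologue or "",
                "zebrafish": ",".join(g.zebrafish_orthologues),
            }
        )
    return GeneAnnotationSim(
        genes=genes,
        orthologues=pd.DataFrame(ortho_rows),
        ccr_genes={genes[i].symbol for i in ccr_idx},
        ens_genes={genes[i].symbol for i in ens_idx},
    )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(cfg: SimConfig, annotation: GeneAnnotationSim):
    """Mouse-array-like log2 expression for the evaluable genes.

    Planted ENS genes get a +log2(``ens_fold_change``) offset in BOTH
    ENS classes relative to the intestine class.  Gaussian noise on the
    log2 scale has gene-wise sds with median ``expr_noise_sd`` and a
    lognormal spread ``expr_noise_sd_spread`` (real probe-summarized
    arrays are strongly heteroscedastic across genes; set the spread to
    0 for a constant sd).  Each array additionally carries a global
    shift with sd ``expr_array_shift_sd`` — the technical effect that
    quantile normalization removes.  Values are missing completely at
    random at rate ``frac_missing``.  Truth is carried in
    ``ExpressionStudy.true_ens``.

    The matrix also carries ``n_array_filler_genes`` non-candidate
    transcripts (rows named ``ARRAY_BGxxxxx``): a transcriptome-wide
    array measures far more genes than the CNV gene universe, and
    quantile normalization is only valid when the bulk of the measured
    probes is non-differential.
    """
    from .expression import ExpressionStudy

    if cfg.n_samples_per_class < 2:
        raise ValueError("need >= 2 samples per class")
    rng = cfg.rng(_STREAM_EXPR)
    gene_ids = [g.symbol for g in annotation.genes if g.mouse_orthologue]
    gene_ids += [f"ARRAY_BG{i:05d}" for i in range(cfg.n_array_filler_genes)]
    n_genes = len(gene_ids)
    classes = (
        ["ENS_GDNF"] * cfg.n_samples_per_class
        + ["ENS_noGDNF"] * cfg.n_samples_per_class
        + ["intestine"] * cfg.n_samples_per_class
    )
    sample_ids = [f"{c}_{i}" for i, c in enumerate(classes)]
    baseline = rng.normal(8.0, 1.5, size=n_genes)
    gene_sd = cfg.expr_noise_sd * 10.0 ** rng.normal(
        0.0, cfg.expr_noise_sd_spread, size=n_genes
    )
    array_shift = rng.normal(0.0, cfg.expr_array_shift_sd, size=len(classes))
    offset = math.log2(cfg.ens_fold_change)
    is_ens = np.array([g in annotation.ens_genes for g in gene_ids])
    mat = np.empty((n_genes, len(classes)))
    for j, cls in enumerate(classes):
        mean = baseline + (offset * is_ens if cls != "intestine" else 0.0)
        mat[:, j] = mean + array_shift[j] + rng.normal(0.0, 1.0, size=n_genes) * gene_sd
    if cfg.frac_missing > 0:
        mask = rng.random(mat.shape) < cfg.frac_missing
        mat[mask] = np.nan
    return ExpressionStudy(
        matrix=pd.DataFrame(mat, index=gene_ids, columns=sample_ids),
        sample_class=pd.Series(classes, index=sample_ids),
        true_ens=set(np.array(gene_ids)[is_ens]),
    )


# ---------------------------------------------------------------------------
# Genotypes and phenotype counts


def simulate_genotypes(
    cfg: SimConfig,
    n_samples: int,
    freqs: Optional[Sequence[float]] = None,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Hardy-Weinberg risk-allele counts at the configured SNPs.

    Counts are Binomial(2, p) per SNP.  ``freqs`` overrides the config
    frequencies (e.g. elevated case frequencies); they must be strictly
    inside (0, 1).
    """
    from .risk import HSCR_RISK_SNPS

    p = tuple(cfg.snp_freqs if freqs is None else freqs)
    if any(not 0.0 < f < 1.0 for f in p):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    rng = cfg.rng(_STREAM_GENO)
    snp_ids = list(HSCR_RISK_SNPS[: len(p)]) + [
        f"snp{i}" for i in range(len(HSCR_RISK_SNPS), len(p))
    ]
    data = {
        snp: rng.binomial(2, f, size=n_samples) for snp, f in zip(snp_ids, p)
    }
    index = [f"{sample_prefix}_{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(data, index=index)


def risk_model_table(cfg: SimConfig) -> pd.DataFrame:
    """The simulated risk model as a (snp, risk_allele, odds_ratio) table."""
    from .risk import HSCR_RISK_SNPS

    snp_ids = list(HSCR_RISK_SNPS[: len(cfg.snp_ors)])
    return pd.DataFrame(
        {"snp": snp_ids, "risk_allele": ["T"] * len(snp_ids), "odds_ratio": cfg.snp_ors}
    )


def simulate_phenotype_counts(cfg: SimConfig) -> pd.DataFrame:
    """Multinomial zebrafish category counts (I-V) per condition."""
    rng = cfg.rng(_STREAM_PHENO)
    rows = {}
    for cond, probs in cfg.phenotype_probs.items():
        rows[cond] = rng.multinomial(cfg.n_larvae_per_condition, probs)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(PHENOTYPE_CATEGORIES)
    )
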
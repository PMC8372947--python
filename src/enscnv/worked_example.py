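"""Published worked example: six HSCR patients with rare CN losses.

This module carries, as plain data, the published candidate-gene table
of a Hirschsprung-disease CNV study: six patients, each with one rare
copy-number loss (coordinates printed 1-based inclusive), the nine
genes inside those losses with their constraint metrics (missense Z,
pLI, deletion single-variant and deletion-CNV dosage scores), the
per-patient non-coding risk score, and the zebrafish orthologues that
were targeted.  Synonymous-Z and duplication scores were not printed
and are stored as missing.

Gene interval coordinates are SYNTHETIC placements inside each
patient's printed CNV region (the table prints CNV boundaries, not
gene coordinates); every derived quantity used downstream (candidate
membership, constraint-rule outcomes) depends only on containment,
which the placements preserve.

It also records the per-group rare-CNV event counts reported for the
full cohort, used for bookkeeping checks.
"""

from __future__ import annotations

from .cnv import CnvCall, GenomicInterval, RarityCall
from .genes import ConstraintMetrics, GeneRecord, annotate_ccr

#: Rare-CNV event counts by patient group and state, as reported for the
#: cohort (three case groups; controls not included here).
RARE_CNV_EVENT_COUNTS: dict[int, dict[str, int]] = {
    1: {"loss": 10, "gain": 8, "hemizygous_loss": 1},
    2: {"loss": 5, "gain": 8},
    3: {"loss": 7, "gain": 12, "homozygous_loss": 4, "hemizygous_loss": 1},
}

#: Size of the external control cohort the study classified rarity against.
CONTROL_COHORT_N = 19_584

# patient, RSnc, CNV region (1-based inclusive), genes with
# (missense Z, pLI, deletion-single, deletion-CNV) metrics and the
# zebrafish orthologues targeted.
_PATIENTS = [
    {
        "patient": "P_000479",
        "rsnc": 4.16,
        "region": ("chr2", 40_624_267, 40_646_501),
        "genes": [("SLC8A1", 2.23, 1.00, -0.02, 0.31, ["slc8a1a", "slc8a1b"])],
    },
    {
        "patient": "P_000512",
        "rsnc": 8.31,
        "region": ("chr6", 28_005_012, 31_683_185),
        "genes": [
            ("TUBB", 5.71, 0.98, -2.85, -1.72, ["tubb5"]),
            ("GNL1", 2.52, 1.00, 1.03, 0.70, ["gnl1"]),
            ("GABBR1", 4.98, 1.00, 1.36, 1.23, ["gabbr1a", "gabbr1b"]),
        ],
    },
    {
        "patient": "P_000537",
        "rsnc": 6.92,
        "region": ("chr10", 49_033_586, 52_431_193),
        "genes": [("MAPK8", 2.92, 1.00, 0.84, -2.25, ["mapk8a", "mapk8b"])],
    },
    {
        "patient": "P_000561",
        "rsnc": 6.08,
        "region": ("chr22", 18_861_209, 21_630_630),
        "genes": [("UFD1L", 2.77, 1.00, 1.06, -2.53, ["ufd1l"])],
    },
    {
        "patient": "P_000567",
        "rsnc": 7.98,
        "region": ("chr17", 58_076_721, 60_362_868),
        "genes": [
            ("TBX2", 1.75, 0.99, -0.01, 0.53, ["tbx2a", "tbx2b"]),
            ("USP32", 3.55, 1.00, -2.85, -0.93, ["usp32"]),
        ],
    },
    {
        "patient": "P_002431",
        "rsnc": 9.37,
        "region": ("chr1", 243_963_527, 244_016_804),
        "genes": [("AKT3", 4.03, 1.00, -2.61, -1.20, ["akt3a", "akt3b"])],
    },
]


def candidate_metrics() -> dict[str, ConstraintMetrics]:
    """Constraint metrics of the nine published candidate genes."""
    out = {}
    for p in _PATIENTS:
        for symbol, mis_z, pli, del_single, del_cnv, _ in p["genes"]:
            out[symbol] = ConstraintMetrics(
                pli=pli, mis_z=mis_z, del_single=del_single, cnv_score=del_cnv
            )
    return out


def rsnc_by_patient() -> dict[str, float]:
    return {p["patient"]: p["rsnc"] for p in _PATIENTS}


def build_worked_example() -> tuple[list[RarityCall], list[GeneRecord]]:
    """Rarity calls and annotated genes reconstructed from the table.

    Each patient contributes one rare loss (absent from the external
    control cohort, frequency 0 over n = 19,584); each gene is placed
    inside its patient's loss (synthetic coordinates), carries the
    printed constraint metrics, is flagged as an ENS gene per the
    table's definition, and lists its zebrafish orthologues.
    """
    calls: list[RarityCall] = []
    genes: list[GeneRecord] = []
    for p in _PATIENTS:
        chrom, start1, end1 = p["region"]
        interval = GenomicInterval(chrom, start1 - 1, end1)  # 1-based -> half-open
        call = CnvCall(
            sample_id=p["patient"], interval=interval, state="loss", group=1
        )
        calls.append(
            RarityCall(
                call=call,
                matched_controls=0,
                control_n=CONTROL_COHORT_N,
                frequency=0.0,
                is_rare=True,
            )
        )
        n = len(p["genes"])
        span = interval.size()
        for k, (symbol, mis_z, pli, del_single, del_cnv, zf) in enumerate(p["genes"]):
            g_start = interval.start + (k + 1) * span // (n + 2)
            g_end = min(g_start + max(1, span // (n + 3)), interval.end)
            genes.append(
                GeneRecord(
                    gene_id=symbol,
                    symbol=symbol,
                    interval=GenomicInterval(chrom, g_start, g_end),
                    mouse_orthologue=symbol.lower().capitalize(),
                    zebrafish_orthologues=list(zf),
                    constraint=ConstraintMetrics(
                        pli=pli, mis_z=mis_z, del_single=del_single, cnv_score=del_cnv
                    ),
                    is_ens_gene=True,
                )
            )
    genes = annotate_ccr(genes)
    return calls, genes
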
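"""Non-coding risk score (RSnc) from predisposing risk-haplotype SNPs.

RSnc for a sample is the weighted allele-count sum

    RSnc = sum_i ln(OR_i) * count_i

over the risk SNPs, where OR_i is the published odds ratio of the risk
allele and count_i in {0, 1, 2} is the number of risk alleles carried.
The six SNPs typically used tag risk haplotypes near RET (rs2506030,
rs7069590, rs2435357), NRG1 (rs7005606) and SEMA3C/D (rs11766001,
rs80227144).  Haplotype-combination interaction effects are not
modelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: The risk-SNP ids customarily genotyped for Hirschsprung disease.
HSCR_RISK_SNPS = (
    "rs2506030",
    "rs7069590",
    "rs2435357",
    "rs7005606",
    "rs11766001",
    "rs80227144",
)

MISSING_POLICIES = ("zero", "impute_mean", "impute_2pq_mean", "fail")


@dataclass(frozen=True)
class RiskSnp:
    snp_id: str
    risk_allele: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be > 0")


@dataclass(frozen=True)
class RiskModel:
    """An ordered collection of risk SNPs with odds-ratio weights."""

    entries: tuple[RiskSnp, ...]

    def __post_init__(self) -> None:
        ids = [e.snp_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in risk model")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def log_or(self, snp_id: str) -> float:
        for e in self.entries:
            if e.snp_id == snp_id:
                return math.log(e.odds_ratio)
        raise KeyError(snp_id)


def read_risk_model(path) -> RiskModel:
    """Read a TSV with columns snp, risk_allele, odds_ratio."""
    df = pd.read_csv(path, sep="\t")
    return RiskModel(
        tuple(
            RiskSnp(str(r.snp), str(r.risk_allele), float(r.odds_ratio))
            for r in df.itertuples(index=False)
        )
    )


def read_genotype_table(path) -> pd.DataFrame:
    """Read a samples-x-SNPs TSV of risk-allele counts (NaN = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.stack().dropna()
    if not bad.isin((0, 1, 2)).all():
        raise ValueError("risk-allele counts must be 0, 1 or 2")
    return df


def rsnc(
    genotypes: Mapping[str, float],
    model: RiskModel,
    missing_policy: str = "zero",
    impute_values: Optional[Mapping[str, float]] = None,
) -> float:
    """RSnc for one sample: sum of ln(OR) * risk-allele count.

    ``genotypes`` maps SNP id -> count in {0, 1, 2} (NaN/absent =
    missing).  Missing policies: ``zero`` contributes 0;
    ``impute_mean`` substitutes ``impute_values[snp]`` (e.g. the cohort
    mean count or the Hardy-Weinberg expectation 2p); ``fail`` raises.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if missing_policy == "impute_2pq_mean":  # alias: impute the HW mean 2p
        missing_policy = "impute_mean"
    total = 0.0
    for entry in model.entries:
        count = genotypes.get(entry.snp_id)
        if count is None or (isinstance(count, float) and math.isnan(count)):
            if missing_policy == "fail":
                raise ValueError(f"missing genotype for {entry.snp_id}")
            if missing_policy == "impute_mean":
                if impute_values is None or entry.snp_id not in impute_values:
                    raise ValueError(
                        f"impute_mean policy needs an impute value for {entry.snp_id}"
                    )
                count = impute_values[entry.snp_id]
            else:
                continue
        if count not in (0, 1, 2) and not (0.0 <= float(count) <= 2.0):
            raise ValueError(f"{entry.snp_id}: allele count {count!r} not in [0, 2]")
        total += math.log(entry.odds_ratio) * float(count)
    return total


def rsnc_table(
    genotypes: pd.DataFrame,
    model: RiskModel,
    missing_policy: str = "zero",
) -> pd.Series:
    """RSnc per sample for a samples-x-SNPs count table.

    With ``impute_mean`` the per-SNP cohort mean count is substituted
    for missing genotypes.
    """
    impute = None
    if missing_policy == "impute_mean":
        impute = genotypes.mean(axis=0, skipna=True).to_dict()
    scores = {
        sample: rsnc(row.dropna().to_dict(), model, missing_policy, impute)
        for sample, row in genotypes.iterrows()
    }
    return pd.Series(scores, name="rsnc")


def group_rsnc_summary(
    scores_by_group: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/sd/n and pairwise pooled two-tailed t-tests.

    Groups with fewer than 2 samples are excluded from testing (logged)
    but still summarized.  Returns (summary, pairwise) DataFrames.
    """
    summary_rows = []
    testable = {}
    for name, values in scores_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        summary_rows.append(
            {
                "group": name,
                "n": len(arr),
                "mean": float(np.mean(arr)) if len(arr) else float("nan"),
                "sd": float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan"),
            }
        )
        if len(arr) >= 2:
            testable[name] = arr
        else:
            log.info("group %s has <2 samples; excluded from t-tests", name)
    pair_rows = []
    for g1, g2 in combinations(testable, 2):
        t, p = stats.ttest_ind(testable[g1], testable[g2], equal_var=True)
        pair_rows.append({"group_a": g1, "group_b": g2, "t": float(t), "p": float(p)})
    return (
        pd.DataFrame(summary_rows).set_index("group"),
        pd.DataFrame(pair_rows, columns=["group_a", "group_b", "t", "p"]),
    )
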
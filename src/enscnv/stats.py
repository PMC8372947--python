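"""Group-comparison and zebrafish phenotype statistics.

Burden profiles, CNV sizes and risk scores are compared across patient
groups with a one-way ANOVA; pairwise two-tailed t-tests follow only
when the ANOVA rejects at 0.05.  Zebrafish enteric-phenotype category
tables (categories I-V, category I = unaffected ENS) are compared with
the "N-1" chi-squared test on the proportion of category-I larvae, and
neuron counts are normalized to gut length (neurons per 100 um) and
compared many-to-one against controls with Dunnett's adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "anova_then_ttests",
    "n1_chisq_2x2",
    "n1_chisq_category_table",
    "neuron_density",
    "dunnett_vs_control",
]


@dataclass
class AnovaResult:
    f: float
    p: float
    pairwise: Optional[pd.DataFrame]  # None when ANOVA did not reject


def _pooled_t(x: np.ndarray, y: np.ndarray, welch: bool) -> tuple[float, float]:
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def anova_then_ttests(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    welch: bool = False,
) -> AnovaResult:
    """One-way ANOVA, with pairwise t-tests gated on ANOVA p < alpha.

    Pairwise tests use the pooled-variance two-tailed t by default
    (``welch=True`` switches to Welch).  Requires >= 2 groups with
    >= 2 values each; all-identical values across all groups leave the
    F statistic undefined and raise.
    """
    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all values identical in all groups; F is undefined")
    f, p = stats.f_oneway(*groups.values())
    pairwise = None
    if p < alpha:
        rows = []
        for g1, g2 in combinations(groups, 2):
            t, tp = _pooled_t(groups[g1], groups[g2], welch)
            rows.append({"group_a": g1, "group_b": g2, "t": t, "p": tp})
        pairwise = pd.DataFrame(rows)
    return AnovaResult(f=float(f), p=float(p), pairwise=pairwise)


def n1_chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """The "N-1" chi-squared test on a 2x2 table [[a, b], [c, d]].

    Statistic = Pearson chi-squared (no continuity correction) scaled
    by (N-1)/N; p from the chi-squared distribution with 1 df.  Raises
    when a row or column margin is zero (statistic undefined).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    n = table.sum()
    if n < 2:
        raise ValueError("need total N >= 2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-squared statistic undefined")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    pearson = float(((table - expected) ** 2 / expected).sum())
    statistic = pearson * (n - 1.0) / n
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def n1_chisq_category_table(
    counts: pd.DataFrame, condition: str, control: str, category_i: str = "I"
) -> tuple[float, float]:
    """"N-1" chi-squared on category-I vs not-I for condition vs control.

    ``counts`` is conditions x categories (I..V).
    """
    cat_i = counts.loc[[condition, control], category_i]
    rest = counts.loc[[condition, control]].drop(columns=category_i).sum(axis=1)
    return n1_chisq_2x2(
        int(cat_i[condition]), int(rest[condition]), int(cat_i[control]), int(rest[control])
    )


def neuron_density(neuron_count: float, gut_length_um: float) -> float:
    """Neurons per 100 um of gut: count / length * 100."""
    if not gut_length_um > 0:
        raise ValueError("gut length must be positive")
    if neuron_count < 0:
        raise ValueError("neuron count must be non-negative")
    return neuron_count / gut_length_um * 100.0


def dunnett_vs_control(
    values_by_group: Mapping[str, Sequence[float]],
    control_label: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons against a control group.

    Family-wise adjusted p-values via Monte-Carlo sampling of the
    max-|t| null under equal group variances: for each draw, group
    means are sampled as independent normals with variance 1/n_i and a
    pooled variance as chi-squared with the residual df; adjusted
    p_i = P(max_j |T_j| >= |t_i|).  Seed-reproducible.
    """
    if control_label not in values_by_group:
        raise ValueError(f"control group {control_label!r} missing")
    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_group.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 values per group")
    control = groups[control_label]
    treatments = {k: v for k, v in groups.items() if k != control_label}
    if not treatments:
        raise ValueError("no treatment groups to compare")

    n_total = sum(len(v) for v in groups.values())
    k_groups = len(groups)
    df_resid = n_total - k_groups
    ss_within = sum(np.sum((v - v.mean()) ** 2) for v in groups.values())
    s2 = ss_within / df_resid

    names = list(treatments)
    t_obs = np.array(
        [
            (treatments[g].mean() - control.mean())
            / np.sqrt(s2 * (1.0 / len(treatments[g]) + 1.0 / len(control)))
            for g in names
        ]
    )

    rng = np.random.default_rng(seed)
    n_c = len(control)
    n_t = np.array([len(treatments[g]) for g in names], dtype=float)
    z_t = rng.standard_normal((n_mc, len(names))) / np.sqrt(n_t)
    z_c = rng.standard_normal((n_mc, 1)) / np.sqrt(n_c)
    s2_null = rng.chisquare(df_resid, size=(n_mc, 1)) / df_resid
    t_null = (z_t - z_c) / np.sqrt(s2_null * (1.0 / n_t + 1.0 / n_c))
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])

    return pd.DataFrame(
        {
            "group": names,
            "mean_diff": [treatments[g].mean() - control.mean() for g in names],
            "t": t_obs,
            "p_adj": p_adj,
        }
    ).set_index("group")
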
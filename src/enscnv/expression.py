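"""Calling "ENS genes" from a labeled log2 expression matrix.

An *ENS gene* is a gene expressed higher in isolated enteric-nervous-
system cells — cultured with and without GDNF — than in whole-intestine
/ other intestinal cells.  The pipeline is: variation/missingness
filtering, quantile normalization, a two-sample t-test moderated by a
random-variance model (RVM), permutation p-values, and a fold-change +
significance rule applied to both ENS-vs-intestine contrasts.

Random-variance model
---------------------
Gene-level precisions are modelled as 1/sigma^2 ~ Gamma(a, b) (shape a,
scale b), under which the scaled residual variances s^2 * a * b follow
an F(m, 2a) distribution across genes, with m the residual degrees of
freedom.  The moderated variance for a gene is

    s_tilde^2 = (m s^2 + 2/b) / (m + 2a)

and the moderated t statistic has m + 2a degrees of freedom.  In the
limit a -> 0, 1/b -> 0 the ordinary pooled two-sample t is recovered.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

CLASSES = ("ENS_GDNF", "ENS_noGDNF", "intestine")


@dataclass
class ExpressionStudy:
    """Genes x samples log2 expression matrix with sample class labels.

    ``matrix`` rows are genes, columns sample ids; NaN marks missing
    values.  ``sample_class`` maps each sample to its class label.
    ``true_ens`` optionally records the planted truth of a synthetic
    study for recovery checks.
    """

    matrix: pd.DataFrame
    sample_class: pd.Series
    true_ens: Optional[set[str]] = None

    def __post_init__(self) -> None:
        self.sample_class = self.sample_class.reindex(self.matrix.columns)
        if self.sample_class.isna().any():
            missing = list(self.sample_class.index[self.sample_class.isna()])
            raise ValueError(f"samples without class label: {missing[:5]}")

    def classes(self) -> list[str]:
        return sorted(self.sample_class.unique())

    def samples_of(self, cls: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == cls])


def read_expression_tsv(matrix_path, classes_path) -> ExpressionStudy:
    """Read a genes-x-samples TSV and a two-column sample->class TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cls = pd.read_csv(classes_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionStudy(matrix=matrix, sample_class=cls)


def average_replicate_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Average rows sharing a gene id (replicate spots within an array)."""
    matrix = study.matrix.groupby(level=0).mean()
    return ExpressionStudy(matrix, study.sample_class, study.true_ens)


# ---------------------------------------------------------------------------
# Filtering and normalization


def filter_genes(
    study: ExpressionStudy,
    fc_frac: float = 0.20,
    fc_thresh: float = 1.5,
    missing_max: float = 0.50,
) -> ExpressionStudy:
    """Drop low-variation and high-missingness genes.

    A gene is retained iff at least ``fc_frac`` of its non-missing
    values deviate from the gene's median by >= log2(``fc_thresh``)
    (a 1.5-fold change in either direction), and fewer than
    ``missing_max`` of samples are missing.
    """
    mat = study.matrix
    log_thresh = math.log2(fc_thresh)
    n = mat.shape[1]
    n_obs = mat.notna().sum(axis=1)
    all_missing = n_obs == 0
    if all_missing.any():
        log.info("excluding %d genes with all values missing", int(all_missing.sum()))
    med = mat.median(axis=1, skipna=True)
    dev = (mat.sub(med, axis=0)).abs() >= log_thresh
    frac_var = dev.sum(axis=1) / n_obs.replace(0, np.nan)
    frac_missing = 1 - n_obs / n
    keep = (frac_var >= fc_frac) & (frac_missing < missing_max) & ~all_missing
    return ExpressionStudy(mat.loc[keep], study.sample_class, study.true_ens)


def quantile_normalize(study: ExpressionStudy, log2_transform: bool = False) -> ExpressionStudy:
    """Quantile-normalize samples to the mean order-statistic curve.

    Each sample's sorted non-missing values are mapped onto the
    across-sample mean of order statistics (reference distribution
    interpolated on a common [0, 1] rank grid when samples differ in
    missingness); ties receive the mean of their tied ranks' targets;
    missing values stay missing.  With ``log2_transform`` the matrix is
    log2-transformed first.
    """
    mat = study.matrix.to_numpy(dtype=float).copy()
    if log2_transform:
        mat = np.log2(mat)
    n_genes, n_samples = mat.shape
    counts = [int(np.sum(~np.isnan(mat[:, j]))) for j in range(n_samples)]
    if any(c < 2 for c in counts):
        bad = study.matrix.columns[[c < 2 for c in counts]]
        raise ValueError(f"samples with <2 non-missing values: {list(bad)}")
    n_ref = max(counts)
    grid = np.linspace(0.0, 1.0, n_ref)
    ref = np.zeros(n_ref)
    for j in range(n_samples):
        vals = np.sort(mat[~np.isnan(mat[:, j]), j])
        p = np.linspace(0.0, 1.0, len(vals))
        ref += np.interp(grid, p, vals)
    ref /= n_samples

    out = np.full_like(mat, np.nan)
    for j in range(n_samples):
        obs = ~np.isnan(mat[:, j])
        vals = mat[obs, j]
        k = len(vals)
        targets = np.interp(np.linspace(0.0, 1.0, k), grid, ref)
        order = np.argsort(vals, kind="mergesort")
        assigned = np.empty(k)
        assigned[order] = targets
        # ties: average the targets assigned to equal values
        sorted_vals = vals[order]
        i = 0
        while i < k:
            j2 = i
            while j2 + 1 < k and sorted_vals[j2 + 1] == sorted_vals[i]:
                j2 += 1
            if j2 > i:
                assigned[order[i : j2 + 1]] = targets[i : j2 + 1].mean()
            i = j2 + 1
        out[obs, j] = assigned
    norm = pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    return ExpressionStudy(norm, study.sample_class, study.true_ens)


# ---------------------------------------------------------------------------
# Random-variance model


@dataclass(frozen=True)
class RvmFit:
    """Fitted inverse-gamma variance prior: 1/sigma^2 ~ Gamma(a, b)."""

    a: float
    b: float
    m: float  # residual df per gene the fit was computed at
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("RVM parameters a and b must be strictly positive")


def fit_rvm(residual_variances: np.ndarray, m: float, tol: float = 1e-8) -> RvmFit:
    """Fit (a, b) by maximum likelihood of s^2 * a * b ~ F(m, 2a).

    ``residual_variances`` are the per-gene pooled variances; ``m`` the
    residual degrees of freedom they were computed with.  Optimization
    is on (log a, log b) from a moment-based start; convergence to
    ``tol`` on the log-likelihood.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValueError("need >= 2 positive residual variances to fit the RVM")
    if np.allclose(s2, s2[0]):
        raise ValueError("all residual variances equal; RVM fit is degenerate")
    if m < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if len(s2) < 50:
        log.warning("RVM fit on only %d genes; >= 50 recommended", len(s2))

    log_s2 = np.log(s2)

    def negloglik(params: np.ndarray) -> float:
        a, b = np.exp(params)
        x_log = log_s2 + math.log(a) + math.log(b)  # log of s2*a*b
        d1, d2 = m, 2.0 * a
        # log F(d1, d2) density at x, evaluated on the log scale
        half1, half2 = d1 / 2.0, d2 / 2.0
        log_pdf = (
            half1 * math.log(d1 / d2)
            - special.betaln(half1, half2)
            + (half1 - 1.0) * x_log
            - (half1 + half2) * np.logaddexp(0.0, x_log + math.log(d1 / d2))
        )
        # Jacobian of s2 -> s2*a*b
        return -(np.sum(log_pdf) + len(s2) * (math.log(a) + math.log(b)))

    # moment start: E[s2] = 1/((a-1) b) under the model, with a0 = 2
    a0 = 2.0
    b0 = 1.0 / ((a0 - 1.0) * float(np.mean(s2)))
    res = optimize.minimize(
        negloglik,
        x0=np.log([a0, b0]),
        method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-8, "maxiter": 20000},
    )
    if not res.success:
        raise RuntimeError(f"RVM fit did not converge: {res.message}")
    a_hat, b_hat = np.exp(res.x)
    return RvmFit(a=float(a_hat), b=float(b_hat), m=float(m), loglik=float(-res.fun))


def simulate_rvm_variances(
    a: float, b: float, m: int, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene residual variances from the RVM (for checks/tests)."""
    precisions = rng.gamma(shape=a, scale=b, size=n_genes)
    return rng.chisquare(m, size=n_genes) / m / precisions


# ---------------------------------------------------------------------------
# Moderated t-tests and permutation p-values


def _class_arrays(study: ExpressionStudy, contrast: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    cls_a, cls_b = contrast
    for c in contrast:
        if c not in set(study.sample_class):
            raise ValueError(f"contrast class {c!r} absent from the study")
    xa = study.matrix[study.samples_of(cls_a)].to_numpy(dtype=float)
    xb = study.matrix[study.samples_of(cls_b)].to_numpy(dtype=float)
    return xa, xb


def _moderated_t(
    xa: np.ndarray, xb: np.ndarray, fit: RvmFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene moderated t on complete cases within classes.

    Returns (t, df, diff, s2_pooled); genes with < 2 observations in a
    class get NaN.
    """
    na = np.sum(~np.isnan(xa), axis=1).astype(float)
    nb = np.sum(~np.isnan(xb), axis=1).astype(float)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        ssa = np.nansum((xa - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((xb - mb[:, None]) ** 2, axis=1)
    m = na + nb - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (ssa + ssb) / m
        s2_shrunk = (m * s2 + 2.0 / fit.b) / (m + 2.0 * fit.a)
        t = (ma - mb) / np.sqrt(s2_shrunk * (1.0 / na + 1.0 / nb))
    df = m + 2.0 * fit.a
    t = np.where(ok, t, np.nan)
    df = np.where(ok, df, np.nan)
    return t, df, ma - mb, np.where(ok, s2, np.nan)


def pooled_residual_variances(
    study: ExpressionStudy, contrast: tuple[str, str]
) -> tuple[np.ndarray, float]:
    """Per-gene pooled within-class variances and the modal residual df."""
    xa, xb = _class_arrays(study, contrast)
    na = np.sum(~np.isnan(xa), axis=1).astype(float)
    nb = np.sum(~np.isnan(xb), axis=1).astype(float)
    ok = (na >= 2) & (nb >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        ssa = np.nansum((xa - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((xb - mb[:, None]) ** 2, axis=1)
    m = na + nb - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(ok, (ssa + ssb) / m, np.nan)
    m_mode = float(xa.shape[1] + xb.shape[1] - 2)
    return s2, m_mode


def rvm_ttest(
    study: ExpressionStudy, contrast: tuple[str, str], fit: RvmFit
) -> pd.DataFrame:
    """Moderated two-sample t-test per gene for one contrast.

    Returns a DataFrame indexed by gene with columns t, df, fold_change
    (linear scale, 2^(mean_A - mean_B)) and the parametric p-value.
    Genes with < 2 non-missing values in a class are skipped (NaN).
    """
    xa, xb = _class_arrays(study, contrast)
    t, df, diff, _ = _moderated_t(xa, xb, fit)
    n_skipped = int(np.isnan(t).sum())
    if n_skipped:
        log.info("rvm_ttest: %d genes skipped (<2 observations in a class)", n_skipped)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"t": t, "df": df, "fold_change": 2.0 ** diff, "p_parametric": p},
        index=study.matrix.index,
    )


def permutation_p(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    fit: RvmFit,
    B: int = 1000,
    seed: int = 0,
    force_monte_carlo: bool = False,
) -> pd.DataFrame:
    """Permutation p-values for the moderated t, per gene.

    Class labels of the contrast's samples are permuted identically
    across genes.  When the number of distinct label assignments is at
    most ``B`` (and ``force_monte_carlo`` is False) all assignments are
    enumerated and p = #{|t*| >= |t|} / n_assignments (the identity
    assignment keeps p > 0).  Otherwise B random permutations are drawn
    and the add-one estimator p = (1 + #{|t*| >= |t|}) / (B + 1) is
    used, so p is never 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cls_a, cls_b = contrast
    samples = study.samples_of(cls_a) + study.samples_of(cls_b)
    na = len(study.samples_of(cls_a))
    x = study.matrix[samples].to_numpy(dtype=float)
    n = len(samples)

    t_obs, _, _, _ = _moderated_t(x[:, :na], x[:, na:], fit)
    # tolerance so exact permutation ties (e.g. the complement assignment,
    # which reproduces |t| up to rounding) are counted consistently
    abs_obs = np.abs(t_obs) - 1e-9

    n_exhaustive = math.comb(n, na)
    exceed = np.zeros(x.shape[0])
    if n_exhaustive <= B and not force_monte_carlo:
        denom = n_exhaustive
        for idx_a in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            t_perm, _, _, _ = _moderated_t(x[:, mask], x[:, ~mask], fit)
            with np.errstate(invalid="ignore"):
                exceed += (np.abs(t_perm) >= abs_obs).astype(float)
        p = exceed / denom
    else:
        rng = np.random.default_rng(seed)
        for _ in range(B):
            perm = rng.permutation(n)
            t_perm, _, _, _ = _moderated_t(x[:, perm[:na]], x[:, perm[na:]], fit)
            with np.errstate(invalid="ignore"):
                exceed += (np.abs(t_perm) >= abs_obs).astype(float)
        p = (1.0 + exceed) / (B + 1.0)
    p = np.where(np.isnan(t_obs), np.nan, p)
    return pd.DataFrame({"t": t_obs, "perm_p": p}, index=study.matrix.index)


# ---------------------------------------------------------------------------
# The full ENS-gene caller


@dataclass
class EnsCallResult:
    """Per-gene results of the two ENS-vs-comparator contrasts."""

    table: pd.DataFrame  # fold_change_/t_/perm_p_ per contrast + is_ens_gene
    fit: RvmFit
    contrasts: tuple[tuple[str, str], ...]

    def ens_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_ens_gene"]])


def call_ens_genes(
    study: ExpressionStudy,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    rule: str = "both",
    comparator: str = "intestine",
    ens_classes: Sequence[str] = ("ENS_GDNF", "ENS_noGDNF"),
    fit: Optional[RvmFit] = None,
) -> EnsCallResult:
    """Flag ENS genes on a filtered, normalized study.

    A gene is an ENS gene when, for BOTH contrasts (each ENS class vs
    the comparator): fold change >= ``fc_min`` in the ENS direction and
    permutation p < ``alpha`` (no multiple-testing correction; the
    significance level is nominal per univariate test).  ``rule="any"``
    relaxes BOTH to at least one contrast.
    """
    if rule not in ("both", "any"):
        raise ValueError("rule must be 'both' or 'any'")
    present = set(study.sample_class)
    for c in (*ens_classes, comparator):
        if c not in present:
            raise ValueError(f"class {c!r} absent from the study")
    contrasts = tuple((ec, comparator) for ec in ens_classes)

    if fit is None:
        s2_all, m_all = [], []
        for contrast in contrasts:
            s2, m = pooled_residual_variances(study, contrast)
            s2_all.append(s2)
            m_all.append(m)
        s2_pooled = np.concatenate(s2_all)
        fit = fit_rvm(s2_pooled[np.isfinite(s2_pooled) & (s2_pooled > 0)], float(np.mean(m_all)))

    table = pd.DataFrame(index=study.matrix.index)
    pass_mask = []
    for k, contrast in enumerate(contrasts):
        tt = rvm_ttest(study, contrast, fit)
        pp = permutation_p(study, contrast, fit, B=B, seed=seed + k)
        suffix = contrast[0]
        table[f"fold_change_{suffix}"] = tt["fold_change"]
        table[f"t_{suffix}"] = tt["t"]
        table[f"perm_p_{suffix}"] = pp["perm_p"]
        pass_mask.append(
            (tt["fold_change"] >= fc_min) & (pp["perm_p"] < alpha) & (tt["t"] > 0)
        )
    combined = pass_mask[0]
    for m_ in pass_mask[1:]:
        combined = (combined & m_) if rule == "both" else (combined | m_)
    table["is_ens_gene"] = combined.fillna(False)
    return EnsCallResult(table=table, fit=fit, contrasts=contrasts)


def ens_pipeline(
    study: ExpressionStudy,
    fc_frac: float = 0.20,
    fc_thresh: float = 1.5,
    missing_max: float = 0.50,
    **call_kwargs,
) -> EnsCallResult:
    """Quantile-normalize -> filter -> fit RVM -> test -> call, in order.

    Normalization runs on the full matrix, before the variation filter:
    it is an array-level preprocessing step, and normalizing only the
    filter's survivors (predominantly differential genes) would absorb
    real class differences into the reference distribution.
    """
    normalized = quantile_normalize(study)
    filtered = filter_genes(
        normalized, fc_frac=fc_frac, fc_thresh=fc_thresh, missing_max=missing_max
    )
    return call_ens_genes(filtered, **call_kwargs)
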
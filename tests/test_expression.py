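"""Filtering, quantile normalization, the RVM moderated t and ENS calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enscnv.expression import (
    ExpressionStudy,
    RvmFit,
    call_ens_genes,
    ens_pipeline,
    filter_genes,
    fit_rvm,
    permutation_p,
    quantile_normalize,
    rvm_ttest,
    simulate_rvm_variances,
)


def _study(matrix, classes):
    cols = [f"s{i}" for i in range(matrix.shape[1])]
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, columns=cols, index=[f"g{i}" for i in range(matrix.shape[0])]),
        sample_class=pd.Series(classes, index=cols),
    )


THREE_V_THREE = ["ENS_GDNF"] * 3 + ["intestine"] * 3


class TestFilterGenes:
    def test_rules_applied_per_gene(self):
        n = 10
        constant = np.full(n, 5.0)
        varying = np.array([0.0, 4.0] * 5)  # every value 2 from the median
        missing = np.full(n, 5.0)
        missing[:6] = np.nan  # 60% missing
        study = _study(
            np.vstack([constant, varying, missing]), ["ENS_GDNF"] * 5 + ["intestine"] * 5
        )
        kept = filter_genes(study).matrix.index
        assert list(kept) == ["g1"]

    def test_matches_direct_rule_evaluation_on_random_genes(self, rng):
        mat = rng.normal(8, 1, size=(1000, 12))
        mat[rng.random(mat.shape) < 0.2] = np.nan
        study = _study(mat, ["ENS_GDNF"] * 4 + ["ENS_noGDNF"] * 4 + ["intestine"] * 4)
        kept = set(filter_genes(study).matrix.index)
        thresh = math.log2(1.5)
        for i, row in enumerate(mat):
            vals = row[~np.isnan(row)]
            expected = (
                len(vals) > 0
                and np.mean(np.abs(vals - np.median(vals)) >= thresh) >= 0.20
                and np.isnan(row).mean() < 0.50
            )
            assert (f"g{i}" in kept) == expected


class TestQuantileNormalize:
    def test_hand_computed_order_statistic_means(self):
        study = _study(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), ["ENS_GDNF", "intestine"])
        out = quantile_normalize(study).matrix.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_samples_unchanged(self):
        col = np.array([1.0, 5.0, 2.0, 9.0])
        study = _study(np.column_stack([col, col, col]), THREE_V_THREE[:3])
        np.testing.assert_allclose(
            quantile_normalize(study).matrix.to_numpy(), np.column_stack([col] * 3)
        )

    def test_complete_samples_share_sorted_vector(self, rng):
        mat = rng.normal(0, 1, size=(50, 6))
        study = _study(mat, THREE_V_THREE)
        out = quantile_normalize(study).matrix.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_missing_values_stay_missing(self, rng):
        mat = rng.normal(0, 1, size=(30, 4))
        mat[3, 1] = np.nan
        study = _study(mat, ["ENS_GDNF", "ENS_GDNF", "intestine", "intestine"])
        out = quantile_normalize(study).matrix.to_numpy()
        assert np.isnan(out[3, 1]) and np.isnan(out).sum() == 1

    def test_ties_get_average_target(self):
        mat = np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]])
        study = _study(mat, ["ENS_GDNF", "intestine"])
        out = quantile_normalize(study).matrix.to_numpy()
        # sample 0 has tied lowest values; both get the mean of ranks 1-2 targets
        assert out[0, 0] == out[1, 0]

    def test_sample_with_too_few_values_errors(self):
        mat = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 4.0]])
        with pytest.raises(ValueError, match="non-missing"):
            quantile_normalize(_study(mat, ["ENS_GDNF", "intestine"]))


class TestFitRvm:
    def test_parameter_recovery_within_ten_percent(self, rng):
        a, b, m = 2.0, 1.5, 8
        s2 = simulate_rvm_variances(a, b, m, 5000, rng)
        fit = fit_rvm(s2, m)
        assert fit.a == pytest.approx(a, rel=0.10)
        assert fit.b == pytest.approx(b, rel=0.10)

    def test_scale_equivariance(self, rng):
        s2 = simulate_rvm_variances(2.5, 0.8, 6, 3000, rng)
        f1 = fit_rvm(s2, 6)
        f2 = fit_rvm(s2 * 4.0, 6)
        assert f2.a == pytest.approx(f1.a, rel=1e-3)
        assert f2.b == pytest.approx(f1.b / 4.0, rel=1e-3)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_rvm(np.array([1.0]), 4)
        with pytest.raises(ValueError):
            fit_rvm(np.full(100, 2.0), 4)


class TestRvmTtest:
    def _fit_weak(self):
        # a -> 0, 1/b -> 0 limit: no shrinkage, classical pooled t
        return RvmFit(a=1e-9, b=1e12, m=4)

    def test_equal_means_give_zero_t_unit_fold(self):
        mat = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = rvm_ttest(_study(mat, THREE_V_THREE), ("ENS_GDNF", "intestine"), self._fit_weak())
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_reduces_to_pooled_t_in_prior_limit(self, rng):
        mat = rng.normal(0, 1, size=(200, 6))
        res = rvm_ttest(_study(mat, THREE_V_THREE), ("ENS_GDNF", "intestine"), self._fit_weak())
        t_ref, p_ref = stats.ttest_ind(mat[:, :3], mat[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, rtol=1e-6)
        np.testing.assert_allclose(res["p_parametric"], p_ref, rtol=1e-5)

    def test_gene_with_one_observation_in_a_class_skipped(self):
        mat = np.array([[1.0, np.nan, np.nan, 4.0, 5.0, 6.0]])
        res = rvm_ttest(_study(mat, THREE_V_THREE), ("ENS_GDNF", "intestine"), self._fit_weak())
        assert np.isnan(res["t"].iloc[0])

    def test_type_one_error_calibrated_under_model_null(self, rng):
        a, b = 2.0, 1.2
        n_genes, n_per = 2000, 5
        m = 2 * n_per - 2
        sigma2 = 1.0 / rng.gamma(a, b, size=n_genes)
        mat = rng.normal(0, 1, size=(n_genes, 2 * n_per)) * np.sqrt(sigma2)[:, None]
        study = _study(mat, ["ENS_GDNF"] * n_per + ["intestine"] * n_per)
        pooled = (
            np.var(mat[:, :n_per], axis=1, ddof=1) * (n_per - 1)
            + np.var(mat[:, n_per:], axis=1, ddof=1) * (n_per - 1)
        ) / m
        fit = fit_rvm(pooled, m)
        res = rvm_ttest(study, ("ENS_GDNF", "intestine"), fit)
        frac = (res["p_parametric"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)


class TestPermutationP:
    def test_addone_convention_bounds(self, rng):
        # strong signal: observed |t| above all permutations -> p = 1/(B+1);
        # 8-vs-8 so a random permutation essentially never redraws the
        # observed class split
        strong = np.concatenate([10.0 + rng.normal(0, 0.05, 8), rng.normal(0, 0.05, 8)])
        mat = np.vstack([strong, rng.normal(0, 1, size=(30, 16))])
        study = _study(mat, ["ENS_GDNF"] * 8 + ["intestine"] * 8)
        fit = RvmFit(a=1.0, b=1.0, m=14)
        B = 200
        res = permutation_p(study, ("ENS_GDNF", "intestine"), fit, B=B, seed=3,
                            force_monte_carlo=True)
        assert res["perm_p"].iloc[0] == pytest.approx(1.0 / (B + 1))
        assert (res["perm_p"] > 0).all() and (res["perm_p"] <= 1).all()

    def test_flat_gene_gets_p_one(self):
        mat = np.vstack([[0.0, 0.0, 0.0, 0.0, 0.0, 0.0], [1, 2, 3, 7, 8, 9.0]])
        study = _study(mat, THREE_V_THREE)
        fit = RvmFit(a=1.0, b=1.0, m=4)
        res = permutation_p(study, ("ENS_GDNF", "intestine"), fit, B=50)
        assert res["perm_p"].iloc[0] == pytest.approx(1.0)

    def test_exhaustive_matches_large_b_monte_carlo(self, rng):
        mat = rng.normal(0, 1, size=(40, 6))
        mat[:10, :3] += 1.5
        study = _study(mat, THREE_V_THREE)
        fit = RvmFit(a=2.0, b=1.0, m=4)
        exact = permutation_p(study, ("ENS_GDNF", "intestine"), fit, B=1000)
        mc = permutation_p(
            study, ("ENS_GDNF", "intestine"), fit, B=4000, seed=11, force_monte_carlo=True
        )
        assert np.max(np.abs(exact["perm_p"] - mc["perm_p"])) < 0.02

    def test_invalid_b(self):
        study = _study(np.zeros((2, 6)), THREE_V_THREE)
        with pytest.raises(ValueError):
            permutation_p(study, ("ENS_GDNF", "intestine"), RvmFit(1, 1, 4), B=0)


class TestCallEnsGenes:
    def _signal_study(self, rng, direction=+1, classes_up=("ENS_GDNF", "ENS_noGDNF")):
        n_bg = 300
        classes = ["ENS_GDNF"] * 4 + ["ENS_noGDNF"] * 4 + ["intestine"] * 4
        mat = rng.normal(8, 0.3, size=(n_bg + 1, 12))
        for j, cls in enumerate(classes):
            if cls in classes_up:
                mat[0, j] += direction * 2.0
        return _study(mat, classes)

    def test_planted_gene_flagged(self, rng):
        res = call_ens_genes(self._signal_study(rng), B=400, seed=0)
        assert res.table["is_ens_gene"].iloc[0]

    def test_higher_in_intestine_never_flagged(self, rng):
        res = call_ens_genes(self._signal_study(rng, direction=-1), B=400, seed=0)
        assert not res.table["is_ens_gene"].iloc[0]

    def test_up_in_single_class_fails_both_rule_but_passes_any(self, rng):
        study = self._signal_study(rng, classes_up=("ENS_GDNF",))
        both = call_ens_genes(study, B=400, seed=0)
        any_rule = call_ens_genes(study, B=400, seed=0, rule="any")
        assert not both.table["is_ens_gene"].iloc[0]
        assert any_rule.table["is_ens_gene"].iloc[0]

    def test_missing_class_errors(self, rng):
        study = _study(rng.normal(0, 1, (10, 6)), THREE_V_THREE)
        with pytest.raises(ValueError, match="absent"):
            call_ens_genes(study, comparator="no_such_class")

    def test_pipeline_idempotent_on_its_own_output(self, rng):
        mat = rng.normal(8, 1.0, size=(400, 12))
        classes = ["ENS_GDNF"] * 4 + ["ENS_noGDNF"] * 4 + ["intestine"] * 4
        study = _study(mat, classes)
        r1 = ens_pipeline(study, B=100, seed=5)
        again = ens_pipeline(study, B=100, seed=5)
        pd.testing.assert_frame_equal(r1.table, again.table)
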
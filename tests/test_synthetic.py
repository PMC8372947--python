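"""The synthetic-study generator: determinism, planted structure, validity."""

import numpy as np
import pandas as pd
import pytest

from enscnv.cnv import classify_cohort
from enscnv.genes import is_ccr
from enscnv.synthetic import (
    PHENOTYPE_CATEGORIES,
    SimConfig,
    simulate_cnv_cohorts,
    simulate_expression,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotype_counts,
)

SMALL = dict(
    n_controls=40,
    n_cases_per_group=(8, 6, 6),
    n_genes=200,
    n_array_filler_genes=100,
)


class TestConfigValidation:
    def test_bad_fractions_and_probs(self):
        with pytest.raises(ValueError):
            SimConfig(frac_ccr=1.5)
        with pytest.raises(ValueError):
            SimConfig(phenotype_probs={"c": (0.5, 0.2, 0.2, 0.05, 0.1)})
        with pytest.raises(ValueError):
            SimConfig(genome=(("chr1", 0),))
        with pytest.raises(ValueError):
            SimConfig(snp_freqs=(0.0, 0.2, 0.3, 0.4, 0.1, 0.2))


class TestCnvCohorts:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(seed=5, **SMALL)
        a = simulate_cnv_cohorts(cfg)
        b = simulate_cnv_cohorts(cfg)
        assert a.cases == b.cases and a.controls == b.controls
        assert a.planted_common_case_idx == b.planted_common_case_idx

    def test_intervals_inside_genome(self):
        cfg = SimConfig(seed=2, **SMALL)
        sim = simulate_cnv_cohorts(cfg)
        lengths = dict(cfg.genome)
        for call in sim.cases + sim.controls:
            iv = call.interval
            assert 0 <= iv.start < iv.end <= lengths[iv.chrom]

    def test_no_cases_degenerate(self):
        cfg = SimConfig(seed=1, n_controls=30, n_cases_per_group=(0, 0, 0))
        sim = simulate_cnv_cohorts(cfg)
        assert sim.cases == [] and len(sim.controls) > 0

    def test_multiplier_one_gives_symmetric_log_sizes(self):
        cfg = SimConfig(seed=3, planted_loss_size_multiplier=1.0, **SMALL)
        sim = simulate_cnv_cohorts(cfg)
        logs = {}
        for call in sim.cases + sim.controls:
            if call.is_loss_like():
                logs.setdefault(call.group, []).append(np.log10(call.interval.size()))
        for g, vals in logs.items():
            # all groups drawn from the same log10-size distribution
            assert abs(np.mean(vals) - cfg.size_log10_mu) < 4 * cfg.size_log10_sigma / np.sqrt(len(vals)) + 0.05

    def test_multiplier_ten_enlarges_group1_losses_across_seeds(self):
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = SimConfig(
                seed=seed, planted_loss_size_multiplier=10.0,
                n_controls=30, n_cases_per_group=(10, 5, 5), n_genes=50,
            )
            sim = simulate_cnv_cohorts(cfg)
            g1 = [c.interval.size() for c in sim.cases if c.group == 1 and c.is_loss_like()]
            ctl = [c.interval.size() for c in sim.controls if c.is_loss_like()]
            if g1 and ctl and np.mean(g1) > np.mean(ctl):
                wins += 1
        assert wins > 95

    def test_planted_common_calls_classify_common(self):
        cfg = SimConfig(seed=4, frac_common_cases=0.3, **SMALL)
        sim = simulate_cnv_cohorts(cfg)
        rcs = classify_cohort(sim.cases, sim.controls, control_n=cfg.n_controls)
        for i in sim.planted_common_case_idx:
            assert not rcs[i].is_rare

    def test_unplanted_calls_mostly_rare(self):
        cfg = SimConfig(seed=4, frac_common_cases=0.0, **SMALL)
        sim = simulate_cnv_cohorts(cfg)
        rcs = classify_cohort(sim.cases, sim.controls, control_n=cfg.n_controls)
        assert np.mean([rc.is_rare for rc in rcs]) > 0.9


class TestGeneAnnotation:
    def test_planted_ccr_fraction_and_rule_consistency(self):
        cfg = SimConfig(seed=1, **SMALL)
        ann = simulate_gene_annotation(cfg)
        flags = [is_ccr(g.constraint) for g in ann.genes]
        assert sum(flags) == int(round(cfg.frac_ccr * cfg.n_genes))
        assert {g.symbol for g, f in zip(ann.genes, flags) if f} == ann.ccr_genes

    def test_extreme_fractions(self):
        none = simulate_gene_annotation(SimConfig(seed=1, frac_ccr=0.0, **SMALL))
        assert not any(is_ccr(g.constraint) for g in none.genes)
        all_ = simulate_gene_annotation(SimConfig(seed=1, frac_ccr=1.0, **SMALL))
        assert all(is_ccr(g.constraint) for g in all_.genes)

    def test_gene_intervals_non_overlapping_and_in_genome(self):
        cfg = SimConfig(seed=2, **SMALL)
        ann = simulate_gene_annotation(cfg)
        by_chrom = {}
        lengths = dict(cfg.genome)
        for g in ann.genes:
            assert 0 <= g.interval.start < g.interval.end <= lengths[g.interval.chrom]
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_zebrafish_orthologue_fraction_binomial(self):
        cfg = SimConfig(seed=3, n_genes=1000, frac_zebrafish_orthologue=0.8)
        ann = simulate_gene_annotation(cfg)
        n_zf = sum(1 for g in ann.genes if g.zebrafish_orthologues)
        # 800 +- 4 binomial sds (sd ~ 12.6)
        assert abs(n_zf - 800) < 4 * np.sqrt(1000 * 0.8 * 0.2)

    def test_ens_truth_only_among_evaluable_genes(self):
        cfg = SimConfig(seed=4, **SMALL)
        ann = simulate_gene_annotation(cfg)
        evaluable = {g.symbol for g in ann.genes if g.mouse_orthologue}
        assert ann.ens_genes <= evaluable


class TestExpression:
    def test_planted_offset_and_missingness(self):
        cfg = SimConfig(seed=5, frac_missing=0.1, **SMALL)
        ann = simulate_gene_annotation(cfg)
        study = simulate_expression(cfg, ann)
        assert study.true_ens == ann.ens_genes
        mat = study.matrix
        frac_na = mat.isna().to_numpy().mean()
        assert frac_na == pytest.approx(0.1, abs=0.02)
        cls = study.sample_class
        ens_rows = mat.loc[sorted(study.true_ens)]
        contrast = (
            ens_rows.loc[:, cls != "intestine"].mean(axis=1)
            - ens_rows.loc[:, cls == "intestine"].mean(axis=1)
        )
        assert contrast.mean() == pytest.approx(np.log2(cfg.ens_fold_change), abs=0.1)

    def test_null_fold_change_means_no_planted_signal(self):
        cfg = SimConfig(seed=6, ens_fold_change=1.0, **SMALL)
        ann = simulate_gene_annotation(cfg)
        study = simulate_expression(cfg, ann)
        mat, cls = study.matrix, study.sample_class
        contrast = (
            mat.loc[:, cls != "intestine"].mean(axis=1)
            - mat.loc[:, cls == "intestine"].mean(axis=1)
        )
        planted = contrast[contrast.index.isin(study.true_ens)]
        background = contrast[~contrast.index.isin(study.true_ens)]
        # per-array shifts move planted and background alike; with fold 1
        # the planted genes carry no extra offset beyond them
        se = np.sqrt(
            planted.var(ddof=1) / len(planted) + background.var(ddof=1) / len(background)
        )
        assert abs(planted.mean() - background.mean()) < 4 * se

    def test_too_few_samples_per_class_errors(self):
        cfg = SimConfig(seed=1, n_samples_per_class=1, **SMALL)
        ann = simulate_gene_annotation(cfg)
        with pytest.raises(ValueError):
            simulate_expression(cfg, ann)


class TestGenotypes:
    def test_mean_allele_count_matches_hardy_weinberg(self):
        cfg = SimConfig(seed=1, snp_freqs=(0.5,) * 6)
        geno = simulate_genotypes(cfg, 5000)
        assert geno.to_numpy().mean() == pytest.approx(1.0, abs=0.02)
        assert set(np.unique(geno.to_numpy())) <= {0, 1, 2}

    def test_boundary_frequency_rejected(self):
        cfg = SimConfig(seed=1)
        with pytest.raises(ValueError):
            simulate_genotypes(cfg, 10, freqs=(0.0, 0.5, 0.5, 0.5, 0.5, 0.5))

    def test_identical_seed_identical_table(self):
        cfg = SimConfig(seed=9)
        pd.testing.assert_frame_equal(
            simulate_genotypes(cfg, 100), simulate_genotypes(cfg, 100)
        )


class TestPhenotypeCounts:
    def test_degenerate_all_category_one(self):
        cfg = SimConfig(
            seed=1, phenotype_probs={"ctl": (1.0, 0, 0, 0, 0)}, n_larvae_per_condition=50
        )
        counts = simulate_phenotype_counts(cfg)
        assert counts.loc["ctl", "I"] == 50
        assert counts.loc["ctl", list("II")].sum() == 0 or counts.shape == (1, 5)

    def test_equal_probabilities_multinomial_spread(self):
        cfg = SimConfig(
            seed=2,
            phenotype_probs={"ctl": (0.2,) * 5},
            n_larvae_per_condition=5000,
        )
        counts = simulate_phenotype_counts(cfg).loc["ctl"]
        sd = np.sqrt(5000 * 0.2 * 0.8)
        assert all(abs(c - 1000) < 3 * sd for c in counts)

    def test_zero_larvae(self):
        cfg = SimConfig(seed=3, n_larvae_per_condition=0)
        assert (simulate_phenotype_counts(cfg).to_numpy() == 0).all()

    def test_columns_are_roman_categories(self):
        counts = simulate_phenotype_counts(SimConfig(seed=1))
        assert tuple(counts.columns) == PHENOTYPE_CATEGORIES


def test_streams_independent_of_each_other():
    """Regenerating one module's data does not depend on another's draws."""
    cfg = SimConfig(seed=11, **SMALL)
    geno_before = simulate_genotypes(cfg, 50)
    simulate_cnv_cohorts(cfg)  # interleave another generator
    geno_after = simulate_genotypes(cfg, 50)
    pd.testing.assert_frame_equal(geno_before, geno_after)
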
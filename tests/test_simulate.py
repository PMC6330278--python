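"""Synthetic-data generator: allele frequencies, LD targets, exact
heritability, scenario semantics and marginal z-scores."""

import numpy as np
import pytest

from sumtwas import (
    ArchitectureConfig,
    ConfigurationError,
    InputError,
    LocusConfig,
    compute_gwas_summary,
    simulate_expression,
    simulate_genotypes,
    simulate_study,
    simulate_trait,
)
from sumtwas.datatypes import GenotypePanel


class TestGenotypes:
    def test_dosages_in_range_and_maf_within_bounds(self):
        cfg = LocusConfig(n_snps=8, maf_range=(0.1, 0.4), ld_rho=0.3, seed=5)
        panel = simulate_genotypes(cfg, 5000)
        assert panel.dosages.min() >= 0 and panel.dosages.max() <= 2
        freq = panel.allele_freq
        assert np.all(freq > 0.1 - 0.03) and np.all(freq < 0.4 + 0.03)

    def test_independent_snps_have_near_zero_correlation(self):
        cfg = LocusConfig(n_snps=10, ld_rho=0.0, seed=11)
        panel = simulate_genotypes(cfg, 5000)
        corr = np.corrcoef(panel.dosages.T)
        off = np.abs(corr[np.triu_indices(10, 1)])
        assert off.mean() < 0.05

    def test_adjacent_dosage_correlation_hits_ld_target(self):
        # 10-replicate average; equal MAFs so the target is attainable
        means = []
        for seed in range(10):
            cfg = LocusConfig(n_snps=10, maf_range=(0.3, 0.3), ld_rho=0.8, seed=seed)
            panel = simulate_genotypes(cfg, 5000)
            corr = np.corrcoef(panel.dosages.T)
            means.append(np.diag(corr, 1).mean())
        assert abs(np.mean(means) - 0.8) < 0.03

    def test_boundary_maf_half(self):
        cfg = LocusConfig(n_snps=6, maf_range=(0.5, 0.5), seed=3)
        panel = simulate_genotypes(cfg, 5000)
        assert np.allclose(panel.allele_freq, 0.5, atol=0.03)

    def test_same_seed_is_byte_identical(self):
        cfg = LocusConfig(n_snps=7, ld_rho=0.5, seed=42)
        a = simulate_genotypes(cfg, 200)
        b = simulate_genotypes(cfg, 200)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snp_ids == b.snp_ids and a.a1 == b.a1

    def test_no_palindromic_allele_pairs(self):
        cfg = LocusConfig(n_snps=50, seed=9)
        panel = simulate_genotypes(cfg, 10)
        for x, y in zip(panel.a1, panel.a2):
            assert {x, y} not in ({"A", "T"}, {"C", "G"})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 0},
            {"n_snps": 3, "maf_range": (0.4, 0.1)},
            {"n_snps": 3, "maf_range": (0.0, 0.3)},
            {"n_snps": 3, "ld_rho": 1.0},
            {"n_snps": 3, "ld_rho": -0.1},
            {"n_snps": 3, "positions": (10, 5, 20)},
        ],
    )
    def test_invalid_locus_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            LocusConfig(**kwargs)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genotypes(LocusConfig(n_snps=3, seed=0), 1)


class TestExpression:
    def test_null_heritability_gives_no_snp_correlation(self, small_panel):
        arch = ArchitectureConfig(n_causal_eqtl=2, cis_h2=0.0, scenario="A")
        expr, weights, _ = simulate_expression(small_panel, arch, seed=1)
        assert np.all(weights == 0)
        corrs = [
            abs(np.corrcoef(small_panel.dosages[:, j], expr)[0, 1])
            for j in range(small_panel.n_snps)
        ]
        assert max(corrs) < 0.08

    def test_full_heritability_single_eqtl_is_collinear(self, small_panel):
        arch = ArchitectureConfig(n_causal_eqtl=1, cis_h2=1.0, scenario="A")
        expr, weights, causal = simulate_expression(small_panel, arch, seed=2)
        j = causal[0]
        assert abs(np.corrcoef(small_panel.dosages[:, j], expr)[0, 1]) > 0.999999

    def test_realized_r2_matches_cis_h2(self, small_panel):
        # effect sizes are rescaled in-sample, so realized R² is exact
        arch = ArchitectureConfig(n_causal_eqtl=3, cis_h2=0.3, scenario="A")
        r2s = []
        for seed in range(50):
            expr, weights, _ = simulate_expression(small_panel, arch, seed=seed)
            g = small_panel.standardized() @ weights
            r2s.append(np.corrcoef(g, expr)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.3) < 0.03
        assert np.allclose(r2s, 0.3, atol=1e-8)

    def test_too_many_causal_snps_rejected(self, small_panel):
        arch = ArchitectureConfig(n_causal_eqtl=small_panel.n_snps + 1, cis_h2=0.2)
        with pytest.raises(ConfigurationError):
            simulate_expression(small_panel, arch, seed=0)

    def test_invalid_cis_h2_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(cis_h2=1.5)


class TestTrait:
    def test_null_scenario_uncorrelated_with_genetic_value(self, small_panel):
        arch = ArchitectureConfig(n_causal_eqtl=3, cis_h2=0.4, scenario="A")
        expr, weights, causal = simulate_expression(small_panel, arch, seed=7)
        g = small_panel.standardized() @ weights
        trait = simulate_trait(small_panel, weights, arch, seed=8, causal_idx=causal)
        assert abs(np.corrcoef(trait, g)[0, 1]) < 0.06

    def test_mediated_scenario_detectable_at_nominal_alpha(self):
        # corr(trait, genetic value) under E with h2t=0.05 at n=5000 should
        # reject the zero-correlation null in the vast majority of replicates
        from scipy.stats import norm as normal

        n, hits = 5000, 0
        n_rep = 200
        arch = ArchitectureConfig(
            n_causal_eqtl=2, cis_h2=0.4, scenario="E", trait_h2_via_expression=0.05
        )
        for seed in range(n_rep):
            cfg = LocusConfig(n_snps=5, ld_rho=0.2, seed=seed)
            panel = simulate_genotypes(cfg, n)
            expr, weights, causal = simulate_expression(panel, arch, seed=seed)
            trait = simulate_trait(panel, weights, arch, seed=seed + 1, causal_idx=causal)
            g = panel.standardized() @ weights
            r = np.corrcoef(trait, g)[0, 1]
            z = np.sqrt(n) * r
            if 2 * normal.sf(abs(z)) < 0.05:
                hits += 1
        assert hits / n_rep > 0.9

    def test_zero_mediation_reduces_to_null(self, small_panel):
        arch = ArchitectureConfig(
            n_causal_eqtl=3, cis_h2=0.4, scenario="E", trait_h2_via_expression=0.0
        )
        expr, weights, causal = simulate_expression(small_panel, arch, seed=4)
        g = small_panel.standardized() @ weights
        trait = simulate_trait(small_panel, weights, arch, seed=5, causal_idx=causal)
        assert abs(np.corrcoef(trait, g)[0, 1]) < 0.06

    def test_mediated_share_is_exact(self, small_panel):
        arch = ArchitectureConfig(
            n_causal_eqtl=3, cis_h2=0.4, scenario="E", trait_h2_via_expression=0.1
        )
        expr, weights, causal = simulate_expression(small_panel, arch, seed=6)
        g = small_panel.standardized() @ weights
        trait = simulate_trait(small_panel, weights, arch, seed=7, causal_idx=causal)
        assert abs(np.corrcoef(trait, g)[0, 1] ** 2 - 0.1) < 1e-8

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(scenario="Z")

    def test_null_scenario_with_mediation_share_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureConfig(scenario="B", trait_h2_via_expression=0.1)

    @pytest.mark.parametrize("scenario", ["C", "D", "F", "G", "H"])
    def test_direct_effect_scenarios_build(self, small_panel, scenario):
        h2t = 0.0 if scenario in "CD" else 0.05
        arch = ArchitectureConfig(
            n_causal_eqtl=2, cis_h2=0.4, scenario=scenario,
            trait_h2_via_expression=h2t, direct_snp_effect=0.05,
        )
        expr, weights, causal = simulate_expression(small_panel, arch, seed=9)
        trait = simulate_trait(small_panel, weights, arch, seed=10, causal_idx=causal)
        assert trait.shape == (small_panel.n_individuals,)
        assert abs(trait.var() - 1.0) < 1e-8
        g = small_panel.standardized() @ weights
        r2 = np.corrcoef(trait, g)[0, 1] ** 2
        if scenario in "CD":
            assert r2 < 0.01  # structurally null
        else:
            assert abs(r2 - h2t) < 1e-8


class TestGwasSummary:
    def test_null_trait_z_is_standard_normal(self, rng):
        # pool 10,000 z-scores over independent null traits
        cfg = LocusConfig(n_snps=100, ld_rho=0.0, seed=77)
        panel = simulate_genotypes(cfg, 2000)
        zs = []
        for _ in range(100):
            trait = rng.standard_normal(panel.n_individuals)
            zs.append(compute_gwas_summary(panel, trait)["Z"].to_numpy())
        zs = np.concatenate(zs)
        frac = np.mean(np.abs(zs) > 1.96)
        assert abs(frac - 0.05) < 0.01

    def test_perfect_association_z_grows_as_sqrt_n(self):
        cfg = LocusConfig(n_snps=4, ld_rho=0.0, seed=21)
        z_by_n = []
        for n in (1000, 4000):
            panel = simulate_genotypes(cfg, n)
            trait = panel.dosages[:, 2].astype(float)
            summ = compute_gwas_summary(panel, trait)
            z_by_n.append(summ["Z"].iloc[2])
        assert z_by_n[1] / z_by_n[0] == pytest.approx(2.0, rel=0.05)

    def test_z_equals_sqrt_n_times_correlation(self, small_panel, rng):
        # moderate-effect identity check
        x = small_panel.standardized()[:, 0]
        trait = 0.1 * x + rng.standard_normal(small_panel.n_individuals)
        summ = compute_gwas_summary(small_panel, trait)
        n = small_panel.n_individuals
        r = np.corrcoef(small_panel.dosages[:, 0], trait)[0, 1]
        assert summ["Z"].iloc[0] == pytest.approx(np.sqrt(n) * r, rel=0.02)

    def test_zero_variance_snp_excluded_with_warning(self, caplog, rng):
        panel = GenotypePanel(
            dosages=np.column_stack(
                [rng.integers(0, 3, 100).astype(float), np.ones(100)]
            ),
            snp_ids=["s1", "s2"],
            chrom=["1", "1"],
            positions=[100, 200],
            a1=["A", "C"],
            a2=["G", "T"],
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="sumtwas.simulate"):
            summ = compute_gwas_summary(panel, rng.standard_normal(100))
        assert list(summ["SNP"]) == ["s1"]
        assert any("zero-variance" in r.message for r in caplog.records)


class TestStudy:
    def test_cohorts_share_snp_identity_and_truth_scores_recovery(self):
        locus = LocusConfig(n_snps=10, ld_rho=0.3, seed=55)
        arch = ArchitectureConfig(n_causal_eqtl=2, cis_h2=0.5, scenario="A")
        study = simulate_study(locus, arch, n_ref=100, n_gwas=300,
                               tissues=("T1", "T2"))
        ref1 = study.reference["T1"]
        assert ref1.panel.snp_ids == study.gwas_panel.snp_ids
        assert ref1.panel.a1 == study.gwas_panel.a1
        assert set(study.truth.causal_idx) <= set(range(10))
        # tissues share causal SNPs (same truth support)
        w1, w2 = study.truth.true_weights["T1"], study.truth.true_weights["T2"]
        assert np.array_equal(w1 != 0, w2 != 0)

    def test_study_is_deterministic(self):
        locus = LocusConfig(n_snps=6, ld_rho=0.2, seed=66)
        arch = ArchitectureConfig(n_causal_eqtl=1, cis_h2=0.3, scenario="A")
        a = simulate_study(locus, arch, n_ref=50, n_gwas=100)
        b = simulate_study(locus, arch, n_ref=50, n_gwas=100)
        assert np.array_equal(a.trait, b.trait)
        assert a.gwas_summary.equals(b.gwas_summary)
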
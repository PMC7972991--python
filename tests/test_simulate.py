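"""Generator correctness: dosage ranges, LD structure, effect calibration,
determinism, and the recoverable variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from mmntwas import erp, genotypes, grex, mixed_model, simulate, twas
from mmntwas.simulate import (
    AGE_GROUPS,
    BRAIN_REGIONS,
    SimConfig,
    simulate_brainspan,
    simulate_erp,
    simulate_genotypes,
    simulate_grm_phenotypes,
    simulate_phenotype,
    simulate_weight_models,
)


class TestGenotypes:
    def test_dosages_are_hard_calls_in_range(self):
        g = simulate_genotypes(SimConfig(n_individuals=100, n_snps=50, seed=1))
        assert g.dosages.shape == (100, 50)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_allele_frequency_matches_maf(self):
        # binomial sampling: SE of the allele frequency is sqrt(0.25/(2n))
        g = simulate_genotypes(
            SimConfig(n_individuals=10000, n_snps=20, maf_range=(0.5, 0.5),
                      ld_block_size=1, seed=2)
        )
        freqs = g.dosages.mean(axis=0) / 2.0
        assert np.all(np.abs(freqs - 0.5) < 0.01)

    def test_ld_free_snps_are_uncorrelated(self):
        g = simulate_genotypes(
            SimConfig(n_individuals=10000, n_snps=50, ld_block_size=1, seed=3)
        )
        corr = np.corrcoef(g.dosages, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.05

    def test_within_block_correlation_positive(self):
        g = simulate_genotypes(
            SimConfig(n_individuals=5000, n_snps=50, ld_block_size=5, seed=4)
        )
        corr = np.corrcoef(g.dosages, rowvar=False)
        block = np.arange(50) // 5
        within = corr[np.equal.outer(block, block) & ~np.eye(50, dtype=bool)]
        assert within.mean() > 0.1
        across = corr[~np.equal.outer(block, block)]
        assert abs(across.mean()) < 0.02

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="maf_range"):
            SimConfig(maf_range=(0.1, 0.6))

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_individuals=50, n_snps=30, seed=9)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)


class TestWeightModels:
    def test_single_snp_model_tracks_dosage(self):
        cfg = SimConfig(n_individuals=200, n_snps=10, n_genes=5, snps_per_gene=1, seed=5)
        g = simulate_genotypes(cfg)
        models, gt = simulate_weight_models(g, cfg)
        # one SNP per gene: the true GReX column is that SNP's dosage rescaled
        for k, gene in enumerate(gt.columns):
            r = np.corrcoef(gt[gene], g.dosages[:, k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-12

    def test_disjoint_ld_free_genes_uncorrelated(self):
        cfg = SimConfig(n_individuals=10000, n_snps=60, ld_block_size=1,
                        n_genes=20, snps_per_gene=3, seed=6)
        g = simulate_genotypes(cfg)
        _, gt = simulate_weight_models(g, cfg)
        corr = np.corrcoef(gt.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() < 0.05

    def test_fit_statistic_is_generating_variance_ratio(self):
        cfg = SimConfig(n_individuals=100, n_snps=20, n_genes=4, snps_per_gene=5, seed=7)
        g = simulate_genotypes(cfg)
        models, _ = simulate_weight_models(g, cfg, target_r2=0.28)
        assert np.allclose(models.table["pred_R2"], 0.28)

    def test_too_many_snps_requested_errors(self):
        cfg = SimConfig(n_individuals=50, n_snps=10, n_genes=5, snps_per_gene=3, seed=8)
        g = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="exceed"):
            simulate_weight_models(g, cfg)


class TestPhenotype:
    def test_unknown_effect_gene_errors(self, small_study):
        cfg = SimConfig(n_individuals=500, effect_genes=[("no_such_gene", 1.0)], seed=1)
        with pytest.raises(ValueError, match="no_such_gene"):
            simulate_phenotype(small_study["grex_true"], cfg)

    def test_null_effects_give_null_associations(self):
        cfg = SimConfig(n_individuals=2000, n_snps=200, n_genes=40, snps_per_gene=5,
                        effect_genes=[], group_effect=0.0,
                        covariate_effects={"age_slope": 0.0, "gender_offset": 0.0,
                                           "stimulus_effect": 0.0, "lab_offsets": {}},
                        noise_sd=1.0, seed=10)
        g = simulate_genotypes(cfg)
        models, gt = simulate_weight_models(g, cfg)
        pheno = simulate_phenotype(gt, cfg)
        resid = twas.adjust_phenotype(pheno, [])
        gx = grex.impute_grex(g, models)
        res = twas.associate_all(gx, resid)
        frac = np.mean(np.abs(res["beta"]) < 3 * res["se"])
        assert frac >= 0.95

    def test_amplitudes_predominantly_negative_at_defaults(self, small_study):
        amp = small_study["phenotypes"]["mmn_amplitude"]
        assert (amp < 0).mean() > 0.6

    def test_variance_decomposition_recoverable(self):
        # amplitude = baseline + 0.82 * centered unit-SD GReX + N(0, 1.5^2)
        cfg = SimConfig(n_individuals=6000, n_snps=50, n_genes=10, snps_per_gene=5,
                        effect_genes=[("gene_0001", 0.82)], group_effect=0.0,
                        covariate_effects={"age_slope": 0.0, "gender_offset": 0.0,
                                           "stimulus_effect": 0.0, "lab_offsets": {}},
                        noise_sd=1.5, seed=11)
        g = simulate_genotypes(cfg)
        _, gt = simulate_weight_models(g, cfg)
        pheno = simulate_phenotype(gt, cfg)
        expected = 0.82**2 * 1.0 + 1.5**2
        observed = pheno["mmn_amplitude"].var()
        assert observed == pytest.approx(expected, rel=0.1)


class TestErpGenerator:
    def test_zero_noise_peak_recovered_exactly(self):
        ep = simulate_erp(-2.5, 150.0, n_trials=10, noise_sd=0.0, seed=0)
        m = erp.measure_epochs(ep, stimulus_class="short")
        assert m.amplitude == -2.5
        assert m.latency == 150.0

    def test_identical_waveforms_give_zero_difference(self):
        ep = simulate_erp(0.0, 150.0, n_trials=5, noise_sd=0.0, seed=0)
        std, dev = erp.average_epochs(ep)
        diff = erp.difference_wave(std, dev)
        assert np.all(diff.values == 0.0)

    def test_noisy_amplitude_within_sem_bound(self):
        ep = simulate_erp(-2.5, 150.0, n_trials=1000, noise_sd=10.0, seed=1)
        m = erp.measure_epochs(ep, stimulus_class="short")
        sem = 10.0 / np.sqrt(1000)
        # trial-averaged noise has SE 10/sqrt(1000) per sample; the windowed
        # minimum is biased slightly downward, hence the 3-SEM slack
        assert abs(m.amplitude - (-2.5)) < 3 * sem

    def test_latency_outside_window_rejected(self):
        with pytest.raises(ValueError, match="latency"):
            simulate_erp(-2.0, 500.0, epoch_window=(-100.0, 400.0))


class TestBrainspan:
    def test_taxonomy_is_nine_by_nine(self):
        atlas = simulate_brainspan(n_genes=50, seed=1)
        assert sorted(atlas.samples["age_group"].unique()) == sorted(AGE_GROUPS)
        assert sorted(atlas.samples["region"].unique()) == sorted(BRAIN_REGIONS)

    def test_injection_raises_signature_score(self):
        from mmntwas import devstage
        atlas = simulate_brainspan(n_genes=100, seed=2,
                                   injected=[("gene_0007", "8-12pcw", 2.0)])
        sig = devstage.age_group_signature(atlas, "8-12pcw")
        assert sig.loc["gene_0007", "signed_score"] > 0

    def test_unknown_injected_gene_errors(self):
        with pytest.raises(ValueError, match="injected gene"):
            simulate_brainspan(n_genes=10, injected=[("gene_9999", "8-12pcw", 1.0)])

    def test_null_signature_pvalues_uniform(self):
        from scipy import stats as sps
        from mmntwas import devstage
        atlas = simulate_brainspan(n_genes=2000, seed=3)
        sig = devstage.age_group_signature(atlas, "19-24pcw")
        ks = sps.kstest(sig["p"], "uniform")
        assert ks.pvalue > 0.01


class TestGrmPhenotypes:
    def test_zero_heritability_estimated_near_zero(self, small_grm):
        ph = simulate_grm_phenotypes(small_grm, 0.0, 0.0, 0.0, seed=4)
        fit = mixed_model.reml_fit(
            ph["trait_a"].to_numpy(), np.ones((len(ph), 1)), small_grm
        )
        assert fit.h2 < 0.1

    def test_shared_genetics_give_unit_correlation(self, small_grm):
        ph = simulate_grm_phenotypes(small_grm, 0.5, 0.5, 1.0, seed=5,
                                     share_genetic_values=True)
        fit = mixed_model.bivariate_reml(
            ph["trait_a"].to_numpy(), ph["trait_b"].to_numpy(),
            np.ones((len(ph), 1)), np.ones((len(ph), 1)), small_grm,
        )
        assert fit.rho_g > 0.9

    def test_non_psd_grm_rejected(self):
        bad = genotypes.KernelMatrix(
            np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"]
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_grm_phenotypes(bad, 0.5, 0.5, 0.0)

    def test_deterministic_under_seed(self, small_grm):
        a = simulate_grm_phenotypes(small_grm, 0.4, 0.3, 0.2, seed=6)
        b = simulate_grm_phenotypes(small_grm, 0.4, 0.3, 0.2, seed=6)
        pd.testing.assert_frame_equal(a, b)
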
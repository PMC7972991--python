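"""Phenotype pre-adjustment, per-gene association, IVW meta-analysis, BH
adjustment, demographic statistics, and the end-to-end TWAS orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mmntwas import grex, simulate, twas
from mmntwas.simulate import SimConfig, simulate_cohort_study
from mmntwas.twas import (
    AssocResult,
    adjust_phenotype,
    associate_all,
    bh_fdr,
    demographic_tests,
    gene_association,
    group_effect_regressions,
    meta_analyze,
    pooled_t_from_summary,
    run_twas,
)


class TestAdjust:
    def test_residuals_orthogonal_to_design(self, small_study):
        pheno = small_study["phenotypes"]
        resid = adjust_phenotype(pheno)
        for col, vals in [
            ("age", pheno["age"]),
            ("patient", (pheno["group"] == "patient").astype(float)),
            ("female", (pheno["gender"] == "female").astype(float)),
        ]:
            r = np.corrcoef(resid, vals)[0, 1]
            assert abs(r) < 1e-10, col

    def test_no_covariates_mean_centers(self, small_study):
        pheno = small_study["phenotypes"]
        resid = adjust_phenotype(pheno, [])
        expected = pheno["mmn_amplitude"] - pheno["mmn_amplitude"].mean()
        assert np.allclose(resid, expected)

    def test_rank_deficient_design_names_alias(self, small_study):
        pheno = small_study["phenotypes"].copy()
        pheno["lab_copy"] = pheno["lab"]
        twas.CATEGORICAL_COVARIATES.add("lab_copy")
        try:
            with pytest.raises(ValueError, match="aliased"):
                adjust_phenotype(pheno, ["lab", "lab_copy"])
        finally:
            twas.CATEGORICAL_COVARIATES.discard("lab_copy")

    def test_residual_variance_matches_generator(self):
        # after adjustment only genetic + noise variance remains
        cfg = SimConfig(n_individuals=6000, n_snps=50, n_genes=10, snps_per_gene=5,
                        effect_genes=[("gene_0001", 0.82)], noise_sd=1.5, seed=20)
        g = simulate.simulate_genotypes(cfg)
        _, gt = simulate.simulate_weight_models(g, cfg)
        pheno = simulate.simulate_phenotype(gt, cfg)
        resid = adjust_phenotype(pheno, ["group", "age", "gender", "lab"])
        assert resid.var() == pytest.approx(0.82**2 + 1.5**2, rel=0.1)


class TestAssociation:
    def test_ci_consistent_with_beta_and_se(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        res = gene_association(x, y)
        assert res.ci95[0] == pytest.approx(res.beta - 1.96 * res.se, abs=1e-9)
        assert res.ci95[1] == pytest.approx(res.beta + 1.96 * res.se, abs=1e-9)

    def test_vectorized_matches_linregress(self, small_study):
        gx = grex.impute_grex(small_study["genotypes"], small_study["models"])
        resid = adjust_phenotype(small_study["phenotypes"])
        table = associate_all(gx, resid)
        frame = gx.to_frame()
        for gene in frame.columns[:5]:
            ref = stats.linregress(frame[gene], resid)
            row = table.set_index("gene").loc[gene]
            assert row["beta"] == pytest.approx(ref.slope, rel=1e-10)
            assert row["se"] == pytest.approx(ref.stderr, rel=1e-10)
            assert row["p"] == pytest.approx(ref.pvalue, rel=1e-8)

    def test_null_pvalues_uniform(self, rng):
        n = 300
        y = rng.standard_normal(n)
        pvals = []
        for _ in range(1000):
            x = rng.standard_normal(n)
            pvals.append(stats.linregress(x, y).pvalue)
        # sanity for the oracle itself, then our vectorized path on shuffled GReX
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError, match="complete pairs"):
            gene_association(rng.standard_normal(5), rng.standard_normal(5))

    def test_zero_variance_grex_gives_na(self):
        res = gene_association(np.ones(50), np.random.default_rng(0).standard_normal(50))
        assert np.isnan(res.beta)


class TestMeta:
    def test_single_cohort_identity(self):
        r = AssocResult.from_estimate("g", "t", "c", 0.5, 0.1, 1e-4, 100)
        pooled = meta_analyze([r])
        assert pooled["beta"] == pytest.approx(0.5)
        assert pooled["se"] == pytest.approx(0.1)

    def test_equal_precision_average(self):
        rs = [
            AssocResult.from_estimate("g", "t", "a", 1.0, 1.0, 0.3, 50),
            AssocResult.from_estimate("g", "t", "b", 0.0, 1.0, 0.9, 50),
        ]
        pooled = meta_analyze(rs)
        assert pooled["beta"] == pytest.approx(0.5, abs=1e-9)
        assert pooled["se"] == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_precision_weighting(self):
        rs = [
            AssocResult.from_estimate("g", "t", "a", 1.0, 0.5, 0.05, 50),
            AssocResult.from_estimate("g", "t", "b", 0.0, 1.0, 0.9, 50),
        ]
        pooled = meta_analyze(rs)
        # weights 4:1 -> beta 0.8, se sqrt(1/5)
        assert pooled["beta"] == pytest.approx(0.8, abs=1e-9)
        assert pooled["se"] == pytest.approx(np.sqrt(0.2), abs=1e-9)

    def test_pooled_se_never_exceeds_best_cohort(self, rng):
        for _ in range(20):
            ses = rng.uniform(0.1, 2.0, size=3)
            rs = [
                AssocResult.from_estimate("g", "t", str(i), rng.normal(), s, 0.5, 50)
                for i, s in enumerate(ses)
            ]
            pooled = meta_analyze(rs)
            assert pooled["se"] <= ses.min() + 1e-12

    def test_all_na_yields_na_row(self):
        rs = [AssocResult("g", "t", "a", np.nan, np.nan, np.nan, (np.nan, np.nan), 50)]
        pooled = meta_analyze(rs)
        assert np.isnan(pooled["beta"]) and pooled["n_cohorts"] == 0


class TestBhFdr:
    def test_headline_example(self):
        # two strong signals among 7933 tests; the rest moderate
        rng = np.random.default_rng(1)
        p = np.concatenate([[1.06e-5, 1.1e-5], rng.uniform(0.01, 1.0, 7931)])
        adj = bh_fdr(p)
        assert adj[0] == pytest.approx(1.1e-5 * 7933 / 2, rel=1e-9)
        assert adj[1] == pytest.approx(1.1e-5 * 7933 / 2, rel=1e-9)
        assert adj[0] <= 0.05 and adj[1] <= 0.05

    def test_all_ones_stay_one(self):
        assert np.all(bh_fdr(np.ones(10)) == 1.0)

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        p = rng.uniform(size=500)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=0.0)

    def test_empty_input(self):
        assert bh_fdr(np.array([])).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr(np.array([0.0, 0.5]))


class TestDemographics:
    def test_yates_chi_square_worked_example(self):
        # 96/206 female/male patients vs 249/177 controls
        rows = []
        for grp, f, m in [("patient", 96, 206), ("control", 249, 177)]:
            rows += [{"group": grp, "gender": "female", "age": 40.0}] * f
            rows += [{"group": grp, "gender": "male", "age": 40.0}] * m
        pheno = pd.DataFrame(rows)
        pheno["age"] += np.random.default_rng(0).normal(0, 10, len(pheno))
        out = demographic_tests(pheno)
        assert out["chi2"] == pytest.approx(49.325, abs=5e-4)
        assert out["n"] == 728

    def test_equal_proportions_give_zero(self):
        rows = []
        for grp in ("patient", "control"):
            rows += [{"group": grp, "gender": "female", "age": 40.0}] * 50
            rows += [{"group": grp, "gender": "male", "age": 40.0}] * 50
        pheno = pd.DataFrame(rows)
        pheno["age"] += np.random.default_rng(1).normal(0, 5, len(pheno))
        assert demographic_tests(pheno)["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_pooled_t_from_printed_summaries(self):
        t, p = pooled_t_from_summary(40.25, 15.28, 426, 38.70, 12.92, 302)
        assert t == pytest.approx(1.436, abs=5e-4)
        assert 0.1 < p < 0.2


class TestGroupRegressions:
    def test_group_effect_recovered(self):
        cfg = SimConfig(n_individuals=3000, n_snps=20, n_genes=4, snps_per_gene=5,
                        effect_genes=[], group_effect=0.70, seed=30)
        g = simulate.simulate_genotypes(cfg)
        _, gt = simulate.simulate_weight_models(g, cfg)
        pheno = simulate.simulate_phenotype(gt, cfg)
        regs = group_effect_regressions(pheno)
        tab = regs["group_whole_sample"].set_index("term")
        term = [t for t in tab.index if "patient" in t][0]
        row = tab.loc[term]
        assert abs(row["coef"] - 0.70) <= 2 * row["se"]

    def test_stimulus_effect_recovered(self):
        cfg = SimConfig(n_individuals=3000, n_snps=20, n_genes=4, snps_per_gene=5,
                        effect_genes=[], seed=31)
        g = simulate.simulate_genotypes(cfg)
        _, gt = simulate.simulate_weight_models(g, cfg)
        pheno = simulate.simulate_phenotype(gt, cfg)
        regs = group_effect_regressions(pheno)
        tab = regs["stimulus_amplitude"].set_index("term")
        term = [t for t in tab.index if "short" in t][0]
        row = tab.loc[term]
        assert abs(row["coef"] - (-1.16)) <= 2 * row["se"]

    def test_null_group_effect(self):
        cfg = SimConfig(n_individuals=2000, n_snps=20, n_genes=4, snps_per_gene=5,
                        effect_genes=[], group_effect=0.0, seed=32)
        g = simulate.simulate_genotypes(cfg)
        _, gt = simulate.simulate_weight_models(g, cfg)
        pheno = simulate.simulate_phenotype(gt, cfg)
        regs = group_effect_regressions(pheno)
        tab = regs["group_whole_sample"].set_index("term")
        term = [t for t in tab.index if "patient" in t][0]
        row = tab.loc[term]
        assert abs(row["coef"]) <= 3 * row["se"]


class TestRunTwas:
    def test_causal_gene_ranks_first(self):
        cfg = SimConfig(n_individuals=1500, n_snps=60, n_genes=12, snps_per_gene=5,
                        effect_genes=[("gene_0003", 0.9)], seed=33)
        cohorts, models, _ = simulate_cohort_study(cfg)
        table = run_twas(cohorts, {"frontal_cortex": models})
        assert table.iloc[0]["gene"] == "gene_0003"
        assert table.iloc[0]["n_cohorts"] == 3

    def test_duplicated_cohort_halves_variance(self, small_study):
        geno = small_study["genotypes"]
        pheno = small_study["phenotypes"]
        models = small_study["models"]
        single = run_twas({"a": {"genotypes": geno, "phenotypes": pheno}},
                          {"frontal_cortex": models})
        double = run_twas(
            {"a": {"genotypes": geno, "phenotypes": pheno},
             "b": {"genotypes": geno, "phenotypes": pheno}},
            {"frontal_cortex": models},
        )
        s = single.set_index("gene")["se"]
        d = double.set_index("gene")["se"].loc[s.index]
        assert np.allclose(d.to_numpy(), s.to_numpy() / np.sqrt(2), rtol=1e-9)

    def test_fdr_pooled_across_both_tissues(self, small_study):
        geno = small_study["genotypes"]
        pheno = small_study["phenotypes"]
        cfg = small_study["config"]
        models_fc = small_study["models"]
        models_cx, _ = simulate.simulate_weight_models(geno, cfg, tissue="cortex")
        table = run_twas(
            {"a": {"genotypes": geno, "phenotypes": pheno}},
            {"frontal_cortex": models_fc, "cortex": models_cx},
        )
        assert set(table["tissue"]) == {"frontal_cortex", "cortex"}
        # the BH pool is the union of both tissues' tests
        expected = bh_fdr(table["p"].to_numpy())
        assert np.allclose(table["fdr"], expected)

    def test_whole_pipeline_coverage_of_true_effect(self):
        """Nominal 95% CIs from the pooled three-cohort analysis cover a
        simulated 0.82 uV effect in >= 93 of 100 replicate runs."""
        hits = 0
        for rep in range(100):
            cfg = SimConfig(n_individuals=4500, n_snps=60, n_genes=12,
                            snps_per_gene=5, effect_genes=[("gene_0001", 0.82)],
                            seed=5000 + rep)
            cohorts, models, _ = simulate_cohort_study(cfg)
            table = run_twas(cohorts, {"frontal_cortex": models})
            row = table.set_index("gene").loc["gene_0001"]
            if abs(row["beta"] - 0.82) <= 2 * row["se"]:
                hits += 1
        assert hits >= 93

    def test_disjoint_cohort_excluded_with_warning(self, small_study):
        geno = small_study["genotypes"]
        pheno = small_study["phenotypes"]
        orphan = pheno.copy()
        orphan.index = ["x" + str(i) for i in range(len(orphan))]
        with pytest.warns(UserWarning, match="no overlapping"):
            table = run_twas(
                {"a": {"genotypes": geno, "phenotypes": pheno},
                 "bad": {"genotypes": geno, "phenotypes": orphan}},
                {"frontal_cortex": small_study["models"]},
            )
        assert table["n_cohorts"].max() == 1
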
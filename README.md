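# mmntwas

A tested, reusable pipeline for transcriptome-wide association analysis of
**mismatch negativity (MMN)** — the negative deflection of the auditory
event-related potential elicited by deviant tones in an oddball sequence —
and its downstream genetic interpretation as a candidate psychosis
endophenotype.

It is aimed at researchers working with multi-site EEG + genotype cohorts
who want to go from averaged event-related potentials and imputed genotype
dosages to: per-gene association statistics for genetically regulated
expression, meta-analyzed and FDR-controlled across cohorts and tissues;
competitive gene-set enrichment; neurodevelopmental expression-signature
enrichment; and SNP-based endophenotype ranking. Because individual-level
study data of this kind are access-controlled, the package ships a
first-class synthetic-data module that generates every input with the
statistical structure the analysis assumes, so the whole pipeline is
testable end to end.

## What it computes

- **ERP extraction** — difference wave (deviant − standard), baseline
  correction, and the windowed negative peak: amplitude = min of the
  difference wave in a cohort-specific window (50–200 ms or 100–250 ms
  post-stimulus), latency = its time.
- **Genetically regulated expression (GReX)** — for gene *g* and individual
  *i*, GReX(i,g) = Σⱼ w₍gⱼ₎ · dosage(i,j) over the SNPs of a
  PredictDB-style weight model, after allele harmonization.
- **TWAS** — per cohort, MMN amplitude pre-adjusted for group, age, gender
  and lab is regressed on each gene's GReX; cohorts are pooled by
  fixed-effect inverse-variance weighting (wⱼ = 1/SEⱼ², pooled SE =
  1/√Σwⱼ) and Benjamini–Hochberg FDR is applied across both cortical
  tissues' gene lists.
- **Mixed-model enrichment** — REML fits of y = Xβ + g + e with
  g ~ N(0, σ_g² K): competitive gene-set enrichment regresses TWAS
  −log₁₀ p on set membership with the gene–gene predicted-expression
  correlation as K; neurodevelopmental enrichment regresses it on signed
  age-group signature scores (sign(effect) × −log₁₀ p) from a
  developmental expression atlas.
- **Endophenotype ranking value** —
  ERV = |√h_i² · √h_e² · ρ_g|, with the illness SNP heritability h_i²
  fixed at a published value (0.2002 by default) and h_e², ρ_g estimated
  by univariate / bivariate GREML on a genomic relationship matrix
  K = ZZᵀ/m over standardized dosages.

## Worked example

Three synthetic cohorts of 1,500 individuals sharing one SNP panel, with
one causal gene at 0.82 μV per SD of predicted expression:

```python
from mmntwas.simulate import SimConfig, simulate_cohort_study
from mmntwas import twas

cfg = SimConfig(n_individuals=4500, n_snps=60, n_genes=12, snps_per_gene=5,
                effect_genes=[("gene_0003", 0.82)], seed=7)
cohorts, models, _ = simulate_cohort_study(cfg)
table = twas.run_twas(cohorts, {"frontal_cortex": models})
print(table.head(3))
```

```
     gene         tissue      beta       se             p  n_cohorts           fdr
gene_0003 frontal_cortex  0.868515 0.038446 5.400807e-113          3 6.480969e-112
gene_0001 frontal_cortex  0.061434 0.044431  1.667648e-01          3  6.670591e-01
gene_0011 frontal_cortex -0.062503 0.044273  1.580197e-01          3  6.670591e-01
```

The causal gene tops the table with a pooled estimate of 0.87 μV/SD
(truth 0.82, within two standard errors); the null genes sit at FDR ≈ 0.67.
The same objects feed the ERP and heritability ends of the pipeline:

```python
from mmntwas.simulate import simulate_erp, simulate_grm_phenotypes, simulate_genotypes
from mmntwas import erp, erv, genotypes

m = erp.measure_epochs(simulate_erp(-2.5, 150.0, n_trials=400, noise_sd=2.0, seed=7),
                       stimulus_class="short")
# -> amplitude -2.816 uV at 155.0 ms (trial noise biases the windowed
#    minimum slightly below the generating -2.5 uV trough)

K = genotypes.compute_grm(simulate_genotypes(SimConfig(
    n_individuals=500, n_snps=1000, ld_block_size=1, n_genes=1,
    snps_per_gene=1, seed=7)))
ph = simulate_grm_phenotypes(K, 0.5, 0.5, 0.7, seed=7)
h2 = erv.greml_h2(ph["trait_a"].to_numpy(), None, K)
rho, rho_se, _ = erv.genetic_correlation(ph["trait_a"].to_numpy(),
                                         ph["trait_b"].to_numpy(), K)
# -> h2_e = 0.399 (SE 0.094); rho_g = 0.612 (SE 0.145); ERV = 0.173
```

with generating values h² = 0.5 and ρ_g = 0.7 — both recovered within two
standard errors at n = 500, and an ERV of 0.173 against the generating
|√0.2002 · √0.5 · 0.7| ≈ 0.221.

A shell interface mirrors the library:
`mmntwas simulate|erp|qc|grm|grex|twas|stats|gsea|devstage|erv --help`.

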
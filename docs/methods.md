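# Methods

This note documents the statistical models implemented in `mmntwas`, the
design of the synthetic-data generators, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## ERP extraction

The MMN is measured from averaged standard and deviant waveforms at a
single Fz-like channel. The pipeline is: pointwise difference
(deviant − standard), baseline correction (subtract the mean over a
pre-stimulus window, default −100 to 0 ms), then the **global minimum**
within a post-stimulus search window. Windows are per-cohort configuration:
50–200 ms for short-stimulus protocols, 100–250 ms for long-stimulus ones,
selected by the phenotype table's stimulus-duration class.

Choices: the peak is the windowed global minimum rather than a
local-extremum criterion (blind visual checks of the original workflow
cannot be automated, so the algorithmic rule is authoritative here); ties
resolve to the earliest latency; amplitudes are read at sample resolution
with no sub-sample interpolation, which keeps zero-noise recovery exact.
Epoch averaging is anchored at the first trial
(`x₀ + mean(x − x₀)`), so identical trials average to themselves without
floating-point drift. Filtering, re-referencing, artifact rejection and
multi-electrode handling are out of scope.

## Genotype QC and the GRM

Dosages count effect (alternate) alleles in [0,2]; missing calls are NaN.
QC removes SNPs by three thresholds — minor allele frequency, missingness
fraction, and Hardy–Weinberg equilibrium tested by a 1-degree-of-freedom
chi-square goodness-of-fit on hard-called genotype counts (defaults 0.01 /
0.05 / 1e-6). A chi-square rather than an exact test keeps the rule
transparent and is adequate at the sample sizes simulated here; an
exact-test option is future work. Every exclusion is logged per criterion.

The genomic relationship matrix is K = ZZᵀ/m over column-standardized
dosages (missing values mean-imputed per SNP first; zero-variance SNPs
excluded with a warning). Standardization makes K invariant to which
allele the dosage counts. Duplicate/twin candidates are flagged at kinship
> 0.95 from this same GRM (no SNP thinning).

## GReX imputation

Predicted expression is the weighted sum of effect-allele dosages over a
gene's model SNPs. Model training is out of scope — weights arrive in a
tabular PredictDB-like dialect (`gene, tissue, rsid, ref_allele,
eff_allele, weight, pred_R2, pred_p`). Harmonization against the genotype
allele metadata: matching alleles keep the weight, swapped alleles flip
its sign (the imputed values then differ by a per-gene additive constant,
absorbed by downstream intercepts, so association slopes are exactly
invariant), irreconcilable pairs are dropped, and strand-ambiguous A/T and
C/G SNPs are dropped by default (overridable). Model SNPs absent from the
genotypes are skipped without reweighting; the per-gene usage fraction is
reported so users can filter poorly covered genes.

## TWAS, meta-analysis, FDR

Covariate adjustment is two-stage: MMN amplitude is residualized by OLS on
clinical group, age, gender and lab (categoricals as indicator contrasts),
and the per-gene model is then a simple regression of residuals on GReX.
This residualization mirrors workflows whose per-gene engine accepts no
covariates; it is performed per cohort, where lab is single-level.
Unaffected relatives are recoded as controls before adjustment.

Cohorts are pooled by fixed-effect inverse-variance weighting
(wⱼ = 1/SEⱼ²; pooled β = Σwβ/Σw; pooled SE = 1/√Σw) with two-sided
p-values from the normal approximation. Genes tested in fewer than all
cohorts are pooled over the cohorts available. BH step-up adjustment runs
once across the union of both tissues' meta-analyzed tests (a gene modeled
in both tissues contributes two tests). Demographic reporting uses the
Yates-corrected chi-square for gender × group and the pooled-variance
two-sample t for age.

## The REML engine

All enrichment and heritability models share one engine for
y = Xβ + g + e, g ~ N(0, σ_g²K), e ~ N(0, σ_e²I). With the
eigendecomposition K = USUᵀ, rotating y and X by Uᵀ diagonalizes the
covariance, and the REML criterion is profiled over the single ratio
δ = σ_e²/σ_g², minimized on log δ ∈ [−10, 10] by bounded scalar search
(tolerance 1e-8). β comes from generalized least squares at the optimum.
A fit is flagged `boundary` when the optimum sits at a search edge **or**
when the profile is flat from the optimum out to an edge (a flat ridge
means the ratio is unidentified, e.g. K ∝ I, where only σ_g²+σ_e² is
estimable). Variance-component covariances (for heritability SEs, delta
method) come from a central-difference observed-information matrix.

The bivariate extension stacks two traits on a shared kernel; after
rotation each eigen-index contributes an independent 2-vector with
covariance sᵢ·Σ_g + Σ_e. The six parameters are optimized directly
(Nelder–Mead on Cholesky factors of Σ_g and Σ_e, positive definite by
construction) rather than by average-information updates — simpler and
adequate at desk scale (n capped at 1,000 by default; every likelihood
evaluation is O(n) after one eigendecomposition). ρ_g = σ_g12/√(σ_g1²σ_g2²)
with a delta-method SE from a numeric information matrix; fits with
|ρ_g| > 0.995 are flagged as boundary (the information matrix degenerates
there and the SE may be undefined).

Wald tests on fixed effects use the normal approximation throughout. The
competitive gene-set test is one-sided (upper tail) by default —
enrichment is directional — while neurodevelopmental signature enrichment
is two-sided by default, since up- and down-regulation are both findings;
both operations expose both flags.

## Competitive gene-set enrichment

Per set: REML regression of TWAS −log₁₀ p on the binary membership
indicator plus intercept, with the gene–gene Pearson correlation of
predicted expression as the random-effect kernel (this absorbs the
LD-induced correlation between nearby genes' statistics). Empirical
correlation matrices need not be positive definite, so eigenvalues are
clipped at 1e-6 and the unit diagonal restored. Sets with fewer than 5
tested genes (intersection with the analyzed genes), or covering all
genes, are skipped — a membership coefficient is inestimable there. BH
adjustment runs across the sets of one tissue, matching per-tissue
reporting.

## Neurodevelopmental signatures

The developmental atlas is genes × samples log₂ RPKM with donor,
age-group (9 bins, 8 weeks post-conception through 30–40 years), region
(9 broad regions) and gender annotations. Lowly expressed genes — below a
threshold in ≥ 90% of samples — are removed first; the threshold is the
literal value 2⁻⁷ on the log₂ scale (an unusual convention, so it is an
exposed parameter).

Per age group, each gene is fit by generalized least squares:

    GEx ~ β₀ + β₁·AgeGr + β₂·AgeGr:CortexRg + β₃·BrainRg + β₄·Gender + ε

and the signature effect is the contrast β₁ + β₂ (age-group shift plus its
interaction with the cortical region of interest); degenerate designs
(single region, no in-group cortex samples) are pruned by rank and the
contrast reduces to the estimable terms. Repeated donors are handled by a
**single common intra-donor correlation ρ**: per-gene OLS residuals are
pooled into a moment estimate of within-donor correlation, averaged across
genes, clipped to [0, 0.95], and folded into an equicorrelated block
covariance whose inverse square root whitens all genes at once. This
two-stage common-ρ scheme is a reproducible simplification of
covariance-incorporating mixed-model fits; it is exact when ρ is shared
across genes. The signed score is sign(effect) × −log₁₀ p (p floored at
1e-300).

Signature enrichment regresses TWAS −log₁₀ p on the signed score with the
expression-correlation kernel (minimum overlap 50 genes). Driver genes are
ranked by the sum of the TWAS significance rank and the |signed score|
rank among genes whose signature sign is concordant with the enrichment
slope, ties broken by gene id — the "rank-based" identification is
otherwise unspecified, so this definition is the package's own.

## Endophenotype ranking

ERV = |√h_i² · √h_e² · ρ_g| ∈ [0, √(h_i²h_e²)]. The illness heritability
is an input constant (default 0.2002, a published liability-scale SNP
heritability of schizophrenia at 0.4% prevalence) and is never estimated;
liability-scale conversion is out of scope. h_e² and ρ_g come from the
REML engine. Rankings report the h_e² and ρ_g standard errors as separate
uncertainty axes rather than a combined ERV SE, and annotate adjacent
entries whose one-SE regions overlap. Case-control liability traits are
simulated as continuous liability proxies; binary-trait GREML with
prevalence adjustment is not reimplemented.

## Synthetic data: what it emulates and what it does not

Defaults encode the pooled study conditions: 728 individuals across three
labs (patient fraction 302/728), a patient–control amplitude difference of
+0.70 μV (patients attenuated), a short-stimulus effect of −1.16 μV, one
causal gene at 0.82 μV per SD of predicted expression, baseline mean
−1.45 μV and residual noise 1.5 μV (so short-stimulus controls sit near
−2.6 μV and long-stimulus ones near −1.5 μV, with mostly negative
amplitudes). Age slope (0.01 μV/yr) and gender offset (0.15 μV) are small
nuisance effects chosen to exercise the adjustment code. MMN latencies are
drawn around 132 ms (short) and 186 ms (long) with 30 ms noise — the
study reports only these two means, so latency calibration is deliberately
loose.

Genotypes are biallelic hard calls: per haplotype, alleles within an LD
block share a latent Gaussian factor (loading √0.6 by default) thresholded
at the allele-frequency quantile, giving positive within-block and zero
across-block correlation. Weight models take disjoint consecutive SNP
subsets by default; raw N(0,1) weights are rescaled so each gene's genetic
component has unit sample variance, making simulated effects interpretable
in μV per SD and letting `impute_grex` reproduce the generator's values
exactly when all model SNPs are present. The recorded prediction R² is the
generating genetic fraction of expression variance (default 0.28). The
multi-cohort generator draws one panel, trains weights once, and splits
individuals round-robin with the lab fixed per cohort.

ERP epochs add i.i.d. Gaussian trial noise to a shared obligatory response
plus, for deviants, a negative Gaussian-shaped deflection truncated at
3.5σ — compact support keeps the difference wave's pre-stimulus baseline
exactly zero, so zero-noise recovery of the trough is exact. The
developmental atlas assigns 42 donors round-robin to the 9 age bins, each
contributing samples from multiple regions (donor random intercepts, SD
0.5, give a true intra-donor correlation of 0.5 at the default residual SD
0.5). Paired GRM traits draw genetic values from N(0, Σ_g ⊗ K) with unit
total variance per trait.

Not emulated: raw continuous EEG and ocular artifacts, genotype-imputation
uncertainty, population stratification or relatedness structure beyond the
GRM, realistic minor-allele-frequency spectra, mouse-to-human ortholog
mapping, and binary disease liabilities. Passing tests therefore
demonstrate statistical correctness of the machinery under the assumed
generative structure, not robustness to the artifacts of real cohorts.

## Problem sizes used in the checks

The calibration and recovery suites run at sizes chosen to make the
sampling distributions informative on a single workstation: the
competitive-enrichment type-I error uses 1,000 null replicates over 500
genes (20-gene sets, kernel estimated from 1,000 individuals of LD-free
genotypes); REML oracle equivalence uses 50 random instances at n ≤ 200;
heritability coverage uses 100 replicates at n = 500 on a GRM from 1,000
LD-free SNPs; pipeline coverage uses 100 replicates of three 1,500-person
cohorts; and bivariate recovery uses n = 500. The whole suite completes in
a few minutes.

## Known limitations

- The bivariate SE is unreliable at the |ρ_g| → 1 boundary (flagged, not
  suppressed).
- The common-ρ GLS for signatures underweights donors whose true
  correlation deviates from the consensus value.
- The competitive-enrichment one-sided test is mildly anti-conservative at
  small gene counts because the −log₁₀ p response is right-skewed; at the
  500-gene scale of the calibration suite the empirical level is within
  the nominal band.
- Meta-analysis is fixed-effect only; no heterogeneity statistics.
- GCTA binary GRM format, genotype imputation, ancestry PCA and model
  training are all out of scope by design.
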
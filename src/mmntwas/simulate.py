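"""Synthetic data generators for every input the analysis pipeline consumes.

The individual-level study data are access-controlled, so testable stand-ins
are generated with the statistical structure the analysis assumes:

* LD-blocked biallelic hard-call dosages (shared latent haplotype factor per
  block, configurable within-block correlation);
* sparse per-gene eQTL weight models scaled so predicted expression has unit
  variance (effects are then in microvolts per SD of expression), with the
  exact genetic expression component returned for oracle comparisons;
* an MMN phenotype built as baseline + genetic component + group / age /
  gender / lab / stimulus-duration effects + Gaussian noise, predominantly
  negative at the defaults;
* ERP epoch sets where the deviant response carries an extra negative
  Gaussian-shaped deflection of known trough amplitude and latency;
* a developmental expression atlas (9 age groups x 9 brain regions, repeated
  donors with random intercepts) with optional injected age-group shifts;
* paired phenotypes with known SNP heritability and genetic correlation on a
  supplied genomic relationship matrix.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KernelMatrix
from .grex import WEIGHT_COLUMNS, WeightModelSet

__all__ = [
    "SimConfig",
    "EpochSet",
    "ExpressionAtlas",
    "AGE_GROUPS",
    "BRAIN_REGIONS",
    "simulate_genotypes",
    "simulate_weight_models",
    "simulate_phenotype",
    "simulate_erp",
    "simulate_brainspan",
    "simulate_grm_phenotypes",
]

# 9 developmental age bins (8 weeks post-conception through 30-40 years) and
# 9 broad brain regions; placeholder taxonomy matching the atlas dimensions.
AGE_GROUPS = [
    "8-12pcw", "13-18pcw", "19-24pcw", "25-38pcw",
    "0-2yr", "3-11yr", "12-19yr", "20-29yr", "30-40yr",
]
BRAIN_REGIONS = [
    "frontal_cortex", "temporal_cortex", "parietal_cortex", "occipital_cortex",
    "hippocampus", "amygdala", "striatum", "thalamus", "cerebellum",
]

_LABS = ("london", "harvard", "maryland")
# Maryland used long (150 ms) deviant stimuli; London and Harvard short (50 ms)
_STIMULUS_CLASS = {"london": "short", "harvard": "short", "maryland": "long"}
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort.

    Sizes follow the pooled analysis sample (728 individuals across three
    labs); the patient-control group effect defaults to +0.70 uV (patients
    attenuated, i.e. less negative), the short-stimulus effect to -1.16 uV,
    and the single default causal gene carries 0.82 uV per SD of predicted
    expression.  ``noise_sd`` is residual amplitude noise in uV.
    """

    n_individuals: int = 728
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.6
    n_genes: int = 40
    snps_per_gene: int = 5
    effect_genes: list[tuple[str, float]] = field(
        default_factory=lambda: [("gene_0001", 0.82)]
    )
    group_effect: float = 0.70
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age_slope": 0.01,       # uV per year
            "gender_offset": 0.15,   # uV added for female participants
            "stimulus_effect": -1.16,  # uV added for short-stimulus labs
            "lab_offsets": {"london": 0.0, "harvard": 0.0, "maryland": 0.0},
        }
    )
    baseline_mean: float = -1.45     # uV; short-stimulus labs then sit near -2.6
    noise_sd: float = 1.5
    patient_fraction: float = 0.41   # 302 / 728
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("n_individuals", "n_snps", "ld_block_size", "n_genes", "snps_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass
class EpochSet:
    """Trial-level standard and deviant epochs sharing one time axis."""

    sampling_rate: float
    epoch_window: tuple[float, float]  # ms, pre-stimulus negative
    standard_epochs: np.ndarray  # trials x time, uV
    deviant_epochs: np.ndarray

    def __post_init__(self):
        if self.standard_epochs.shape[1] != self.deviant_epochs.shape[1]:
            raise ValueError("standard and deviant epochs must share the time axis")
        lo, hi = self.epoch_window
        if lo > -100 or hi < 300:
            raise ValueError("epoch window must cover at least -100 to +300 ms")

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        n = self.standard_epochs.shape[1]
        return self.epoch_window[0] + step * np.arange(n)


@dataclass
class ExpressionAtlas:
    """Genes x samples log2 expression with donor/age/region/gender labels."""

    expression: pd.DataFrame  # genes x samples, log2 RPKM
    samples: pd.DataFrame     # sample_id, donor, age_group, region, gender
    cortex_region: str = "frontal_cortex"

    def __post_init__(self):
        if list(self.expression.columns) != list(self.samples["sample_id"]):
            raise ValueError("expression columns must match sample annotation order")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hard-called dosages in {0,1,2} with block LD structure.

    Each haplotype's alleles within a block share a latent Gaussian factor
    (loading sqrt(ld_rho)), thresholded at the allele frequency quantile, so
    within-block allele correlation is positive and blocks are independent.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)
    block = np.arange(m) // config.ld_block_size
    n_blocks = int(block[-1]) + 1
    dosages = np.zeros((n, m))
    rho = config.ld_rho
    for _hap in range(2):
        z_block = rng.standard_normal((n, n_blocks))
        z_snp = rng.standard_normal((n, m))
        latent = np.sqrt(rho) * z_block[:, block] + np.sqrt(1 - rho) * z_snp
        dosages += (latent < thresholds).astype(float)
    pair = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "id": [f"snp_{j+1:05d}" for j in range(m)],
            "chrom": (block + 1).astype(str),
            "pos": 1000 * (np.arange(m) + 1),
            "effect_allele": [p[0] for p in pair],
            "other_allele": [p[1] for p in pair],
            "freq": mafs,
        }
    )
    samples = [f"ind_{i+1:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, samples)


# ---------------------------------------------------------------------------
# Weight models and true GReX
# ---------------------------------------------------------------------------


def simulate_weight_models(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    *,
    tissue: str = "frontal_cortex",
    overlapping: bool = False,
    target_r2: float = 0.28,
) -> tuple[WeightModelSet, pd.DataFrame]:
    """Sparse per-gene SNP weights plus the exact genetic expression matrix.

    Genes take disjoint consecutive SNP subsets by default (set
    ``overlapping=True`` to sample subsets with replacement across genes).
    Raw weights are N(0,1) draws rescaled so each gene's genetic component
    has unit sample variance; the recorded prediction R^2 is the fraction of
    simulated total expression variance explained by the genetic component,
    with an F-test p-value at the nominal reference-panel size.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = genotypes.n_snps
    spg = config.snps_per_gene
    if spg > m:
        raise ValueError("snps_per_gene exceeds available SNPs")
    if not overlapping and config.n_genes * spg > m:
        raise ValueError(
            f"{config.n_genes} genes x {spg} SNPs exceed {m} available SNPs; "
            "use overlapping=True or enlarge n_snps"
        )
    genes = [f"gene_{k+1:04d}" for k in range(config.n_genes)]
    rows = []
    grex_cols = {}
    n_ref = 500  # nominal reference transcriptome panel size for the fit p-value
    for k, gene in enumerate(genes):
        if overlapping:
            idx = rng.choice(m, size=spg, replace=False)
        else:
            idx = np.arange(k * spg, (k + 1) * spg)
        w = rng.standard_normal(spg)
        raw = genotypes.dosages[:, idx] @ w
        sd = raw.std(ddof=0)
        if sd > 0:
            w = w / sd
            raw = raw / sd
        # genetic fraction of simulated expression variance in the generating model
        noise_var = (1.0 - target_r2) / target_r2
        r2 = 1.0 / (1.0 + noise_var)
        f_stat = r2 / (1 - r2) * (n_ref - 2)
        pred_p = float(stats.f.sf(f_stat, 1, n_ref - 2))
        grex_cols[gene] = raw
        sub = genotypes.variants.iloc[idx]
        for snp_id, eff, oth, wj in zip(
            sub["id"], sub["effect_allele"], sub["other_allele"], w
        ):
            rows.append((gene, tissue, snp_id, oth, eff, wj, r2, pred_p))
    table = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    grex_true = pd.DataFrame(grex_cols, index=genotypes.samples)
    return WeightModelSet(table), grex_true


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------


def simulate_phenotype(
    grex_true: pd.DataFrame, config: SimConfig, *, lab: str | None = None
) -> pd.DataFrame:
    """MMN phenotype table with group, age, gender, lab and genetic effects.

    Amplitude (uV, predominantly negative) is baseline + per-gene genetic
    effects + group/age/gender/lab/stimulus effects + N(0, noise_sd) noise.
    London contributes a 'relative' group (downstream analysis recodes
    relatives as controls).  Latency (ms) gets the long-stimulus delay plus
    noise so the latency regressions have realistic structure.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(grex_true)
    if config.n_individuals != n:
        raise ValueError("grex_true rows do not match n_individuals")
    for gene, _ in config.effect_genes:
        if gene not in grex_true.columns:
            raise ValueError(f"effect gene {gene!r} absent from grex_true")

    if lab is None:
        lab = rng.choice(_LABS, size=n, p=[0.35, 0.10, 0.55])
    else:
        if lab not in _LABS:
            raise ValueError(f"unknown lab {lab!r}")
        lab = np.full(n, lab)
    stimulus = np.array([_STIMULUS_CLASS[l] for l in lab])
    group = np.where(rng.random(n) < config.patient_fraction, "patient", "control")
    # some London controls are unaffected relatives of patients
    relative = (lab == "london") & (group == "control") & (rng.random(n) < 0.3)
    group = np.where(relative, "relative", group)
    age = np.clip(rng.normal(40, 14, size=n), 18, 80)
    gender = np.where(rng.random(n) < 0.5, "female", "male")

    cov = config.covariate_effects
    amplitude = np.full(n, config.baseline_mean)
    for gene, eff in config.effect_genes:
        gvals = grex_true[gene].to_numpy()
        amplitude += eff * (gvals - gvals.mean())  # centered: baseline stays interpretable
    amplitude += np.where(group == "patient", config.group_effect, 0.0)
    amplitude += cov.get("age_slope", 0.0) * (age - 40.0)
    amplitude += np.where(gender == "female", cov.get("gender_offset", 0.0), 0.0)
    amplitude += np.where(stimulus == "short", cov.get("stimulus_effect", 0.0), 0.0)
    offsets = cov.get("lab_offsets", {})
    amplitude += np.array([offsets.get(l, 0.0) for l in lab])
    amplitude += rng.normal(0.0, config.noise_sd, size=n)

    latency = np.where(stimulus == "long", 186.0, 132.0) + rng.normal(0, 30, size=n)
    return pd.DataFrame(
        {
            "id": grex_true.index,
            "mmn_amplitude": amplitude,
            "mmn_latency": latency,
            "group": group,
            "age": age,
            "gender": gender,
            "lab": lab,
            "stimulus_class": stimulus,
        }
    ).set_index("id", drop=False)


def simulate_cohort_study(
    config: SimConfig,
    cohort_labs: tuple[str, ...] = ("london", "harvard", "maryland"),
) -> tuple[dict, "WeightModelSet", pd.DataFrame]:
    """Multi-cohort study sharing one SNP panel and one weight-model set.

    Genotypes for all ``config.n_individuals`` are drawn from a single
    panel, weight models are trained once against it, and the individuals
    are split round-robin into one cohort per lab (each cohort's phenotypes
    generated with that lab fixed, as in the real multi-site design).
    Returns ``(cohorts, models, grex_true)`` with ``cohorts`` in the layout
    :func:`mmntwas.twas.run_twas` expects.
    """
    from dataclasses import replace

    geno = simulate_genotypes(config)
    models, grex_true = simulate_weight_models(geno, config)
    n = config.n_individuals
    k = len(cohort_labs)
    cohorts = {}
    for c, lab in enumerate(cohort_labs):
        idx = np.arange(c, n, k)
        sub = GenotypeMatrix(
            geno.dosages[idx],
            geno.variants.copy(),
            [geno.samples[i] for i in idx],
        )
        sub_cfg = replace(config, n_individuals=len(idx), seed=config.seed + 101 + c)
        pheno = simulate_phenotype(grex_true.iloc[idx], sub_cfg, lab=lab)
        cohorts[lab] = {"genotypes": sub, "phenotypes": pheno}
    return cohorts, models, grex_true


# ---------------------------------------------------------------------------
# ERP epochs
# ---------------------------------------------------------------------------


def simulate_erp(
    peak_amplitude: float,
    peak_latency: float,
    n_trials: int = 200,
    noise_sd: float = 5.0,
    seed: int = 0,
    *,
    sampling_rate: float = 1000.0,
    epoch_window: tuple[float, float] = (-100.0, 300.0),
    peak_width: float = 25.0,
) -> EpochSet:
    """Epochs whose deviant waveform carries an extra negative deflection.

    The deviant generating waveform is the standard waveform plus a Gaussian
    trough centred at ``peak_latency`` (ms post-stimulus) with depth
    ``peak_amplitude`` (uV, signed; pass a negative value for the usual MMN).
    Trial noise is i.i.d. Gaussian per sample.
    """
    lo, hi = epoch_window
    if not (lo <= peak_latency <= hi):
        raise ValueError(f"peak latency {peak_latency} ms outside epoch window {epoch_window}")
    step = 1000.0 / sampling_rate
    times = np.arange(lo, hi + 0.5 * step, step)
    rng = np.random.default_rng(seed)
    # shared obligatory auditory response (cancels exactly in the difference wave)
    standard_wave = 1.2 * np.exp(-0.5 * ((times - 90.0) / 35.0) ** 2)
    z = (times - peak_latency) / peak_width
    # compact support (truncated at 3.5 sigma) keeps the pre-stimulus baseline
    # of the difference wave exactly zero, so zero-noise recovery is exact
    deflection = np.where(np.abs(z) <= 3.5, peak_amplitude * np.exp(-0.5 * z**2), 0.0)
    deviant_wave = standard_wave + deflection
    std_epochs = standard_wave + rng.normal(0, noise_sd, size=(n_trials, times.size))
    dev_epochs = deviant_wave + rng.normal(0, noise_sd, size=(n_trials, times.size))
    return EpochSet(sampling_rate, (lo, hi), std_epochs, dev_epochs)


# ---------------------------------------------------------------------------
# Developmental atlas
# ---------------------------------------------------------------------------


def simulate_brainspan(
    n_genes: int = 500,
    donors: int = 42,
    seed: int = 0,
    injected: list[tuple[str, str, float]] | None = None,
    *,
    regions_per_donor: int = 9,
    donor_sd: float = 0.5,
    residual_sd: float = 0.5,
    cortex_region: str = "frontal_cortex",
) -> ExpressionAtlas:
    """Developmental atlas: log2 expression with repeated donors.

    Donors are assigned to the 9 age groups round-robin and each contributes
    samples from ``regions_per_donor`` regions, giving donor-level repeated
    measures.  Expression = gene baseline + gene-specific region and gender
    effects + donor random intercept + residual noise, plus any injected
    (gene, age_group, shift) effects applied to all of that age group's
    samples.
    """
    injected = injected or []
    rng = np.random.default_rng(seed)
    genes = [f"gene_{k+1:04d}" for k in range(n_genes)]
    gene_pos = {g: k for k, g in enumerate(genes)}
    for gene, age_group, _ in injected:
        if gene not in gene_pos:
            raise ValueError(f"injected gene {gene!r} not in atlas")
        if age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {age_group!r}")

    donor_age = [AGE_GROUPS[d % len(AGE_GROUPS)] for d in range(donors)]
    donor_gender = ["female" if d % 2 else "male" for d in range(donors)]
    records = []
    for d in range(donors):
        if regions_per_donor >= len(BRAIN_REGIONS):
            regs = list(BRAIN_REGIONS)
        else:
            regs = list(rng.choice(BRAIN_REGIONS, size=regions_per_donor, replace=False))
        for r in regs:
            records.append((f"sample_{len(records)+1:04d}", f"donor_{d+1:02d}", donor_age[d], r, donor_gender[d]))
    samples = pd.DataFrame(records, columns=["sample_id", "donor", "age_group", "region", "gender"])
    n_s = len(samples)

    baseline = rng.normal(5.0, 2.0, size=n_genes)
    region_eff = rng.normal(0.0, 0.3, size=(n_genes, len(BRAIN_REGIONS)))
    gender_eff = rng.normal(0.0, 0.1, size=n_genes)
    donor_int = rng.normal(0.0, donor_sd, size=(n_genes, donors))

    region_idx = samples["region"].map({r: i for i, r in enumerate(BRAIN_REGIONS)}).to_numpy()
    donor_idx = samples["donor"].map(
        {f"donor_{d+1:02d}": d for d in range(donors)}
    ).to_numpy()
    female = (samples["gender"] == "female").to_numpy()

    expr = (
        baseline[:, None]
        + region_eff[:, region_idx]
        + np.where(female, gender_eff[:, None], 0.0)
        + donor_int[:, donor_idx]
        + rng.normal(0.0, residual_sd, size=(n_genes, n_s))
    )
    age_arr = samples["age_group"].to_numpy()
    for gene, age_group, shift in injected:
        expr[gene_pos[gene], age_arr == age_group] += shift

    expression = pd.DataFrame(expr, index=genes, columns=samples["sample_id"])
    return ExpressionAtlas(expression, samples, cortex_region=cortex_region)


# ---------------------------------------------------------------------------
# Paired phenotypes on a GRM
# ---------------------------------------------------------------------------


def simulate_grm_phenotypes(
    grm: KernelMatrix,
    h2_a: float,
    h2_b: float,
    rho_g: float,
    seed: int = 0,
    *,
    share_genetic_values: bool = False,
) -> pd.DataFrame:
    """Two unit-variance traits y = g + e with known h^2 and rho_g on a GRM.

    Genetic values are drawn jointly from N(0, Sigma_g (x) K) with
    Sigma_g = [[h2_a, rho_g sqrt(h2_a h2_b)], [., h2_b]]; environmental
    residuals are independent with variances 1 - h2.  With
    ``share_genetic_values=True`` both traits reuse one genetic draw scaled
    to the two heritabilities (rho_g exactly 1 by construction).
    """
    for name, v in (("h2_a", h2_a), ("h2_b", h2_b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if not -1.0 <= rho_g <= 1.0:
        raise ValueError("rho_g must be in [-1, 1]")
    K = grm.values
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-8:
        raise ValueError("GRM is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    n = K.shape[0]
    rng = np.random.default_rng(seed)
    root = U * np.sqrt(s)  # K^(1/2) up to rotation

    if share_genetic_values:
        z = rng.standard_normal(n)
        base = root @ z
        g1 = np.sqrt(h2_a) * base
        g2 = np.sqrt(h2_b) * base
    else:
        sigma_g = np.array(
            [
                [h2_a, rho_g * np.sqrt(h2_a * h2_b)],
                [rho_g * np.sqrt(h2_a * h2_b), h2_b],
            ]
        )
        # PSD square root of the 2x2 cross-trait covariance
        w, V = np.linalg.eigh(sigma_g)
        L = V * np.sqrt(np.clip(w, 0.0, None)) @ V.T
        z = rng.standard_normal((n, 2))
        g = root @ z @ L.T
        g1, g2 = g[:, 0], g[:, 1]
    e1 = rng.normal(0.0, np.sqrt(max(1.0 - h2_a, 0.0)), size=n)
    e2 = rng.normal(0.0, np.sqrt(max(1.0 - h2_b, 0.0)), size=n)
    return pd.DataFrame(
        {"id": grm.ids, "trait_a": g1 + e1, "trait_b": g2 + e2}
    ).set_index("id", drop=False)
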
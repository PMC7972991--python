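"""Neurodevelopmental expression signatures and their enrichment in TWAS hits.

A developmental expression atlas (genes x samples, log2 RPKM, with donor,
age-group, brain-region and gender annotations) is reduced to per-gene,
per-age-group "signatures": the contrast beta1 + beta2 from

    GEx ~ b0 + b1*AgeGr + b2*AgeGr:CortexRg + b3*BrainRg + b4*Gender + e

where AgeGr indicates membership of the age group of interest and CortexRg
the cortical region of interest.  Repeated samples from the same donor are
correlated; a single common intra-donor correlation rho is estimated from
per-gene residual moments and folded into a block covariance for generalized
least squares.  The signed signature score sign(effect) * -log10(p) then
enters a mixed-model enrichment regression against the TWAS -log10 p-values
(gene-gene expression correlation as the random effect), asking whether
MMN-associated genes are up- or down-regulated at each developmental stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import KernelMatrix
from .mixed_model import kernel_eig, reml_fit, wald_one_sided
from .simulate import ExpressionAtlas

__all__ = [
    "filter_low_expression",
    "estimate_intra_donor_rho",
    "age_group_signature",
    "signature_enrichment",
    "top_driver_genes",
]

# literal reading of the published low-expression rule: log2 RPKM below 2^-7
DEFAULT_LOW_EXPR_THRESHOLD = 2.0 ** -7
DEFAULT_LOW_EXPR_FRACTION = 0.9
P_FLOOR = 1e-300


def filter_low_expression(
    atlas: ExpressionAtlas,
    threshold: float = DEFAULT_LOW_EXPR_THRESHOLD,
    fraction: float = DEFAULT_LOW_EXPR_FRACTION,
) -> ExpressionAtlas:
    """Drop genes whose log2 expression is below ``threshold`` in at least
    ``fraction`` of samples.  Idempotent; warns if nothing survives."""
    expr = atlas.expression
    low = (expr.to_numpy() < threshold).mean(axis=1) >= fraction
    kept = expr.loc[~low]
    if kept.empty:
        warnings.warn("low-expression filter removed every gene", UserWarning)
    return ExpressionAtlas(kept, atlas.samples, cortex_region=atlas.cortex_region)


def _signature_design(samples: pd.DataFrame, age_group: str, cortex_region: str):
    """Design matrix for the signature model with degenerate columns pruned.

    Returns (X, contrast weights) where the contrast selects the age-group
    coefficient plus the age-by-cortex interaction when both are estimable.
    """
    if age_group not in set(samples["age_group"]):
        raise ValueError(f"age group {age_group!r} absent from the atlas")
    n = len(samples)
    age = (samples["age_group"] == age_group).to_numpy(dtype=float)
    cortex = (samples["region"] == cortex_region).to_numpy(dtype=float)
    cols = [np.ones(n), age, age * cortex]
    names = ["intercept", "age_group", "age_group:cortex"]
    regions = sorted(samples["region"].unique())
    for r in regions[1:]:
        cols.append((samples["region"] == r).to_numpy(dtype=float))
        names.append(f"region[{r}]")
    genders = sorted(samples["gender"].unique())
    for g in genders[1:]:
        cols.append((samples["gender"] == g).to_numpy(dtype=float))
        names.append(f"gender[{g}]")
    X = np.column_stack(cols)
    # prune zero and collinear columns, never the intercept or age_group term
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    X = X[:, keep]
    kept_names = [names[j] for j in keep]
    contrast = np.zeros(len(keep))
    contrast[kept_names.index("age_group")] = 1.0
    if "age_group:cortex" in kept_names:
        contrast[kept_names.index("age_group:cortex")] = 1.0
    return X, contrast, kept_names


def estimate_intra_donor_rho(atlas: ExpressionAtlas, age_group: str | None = None) -> float:
    """Common intra-donor residual correlation, by moments.

    Per gene, OLS residuals from the signature design (using the first age
    group if none is given) are pooled within donors:
    rho_gene = sum over donors of the off-diagonal residual products divided
    by (residual variance x number of ordered pairs).  The per-gene moment
    estimates are averaged and clipped to [0, 0.95].
    """
    samples = atlas.samples
    ag = age_group if age_group is not None else samples["age_group"].iloc[0]
    X, _, _ = _signature_design(samples, ag, atlas.cortex_region)
    Y = atlas.expression.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta  # residuals, samples x genes
    donors = samples["donor"].to_numpy()
    num = np.zeros(R.shape[1])
    pair_count = 0
    for d in pd.unique(donors):
        idx = np.flatnonzero(donors == d)
        k = idx.size
        if k < 2:
            continue
        block = R[idx]
        sums = block.sum(axis=0)
        num += sums * sums - (block * block).sum(axis=0)
        pair_count += k * (k - 1)
    if pair_count == 0:
        return 0.0
    var = R.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_gene = num / (pair_count * var)
    rho = float(np.nanmean(rho_gene))
    return float(np.clip(rho, 0.0, 0.95))


def _donor_whitener(samples: pd.DataFrame, rho: float) -> np.ndarray:
    """Inverse square root of the block covariance with unit diagonal and
    intra-donor correlation rho (analytic per equicorrelated block)."""
    n = len(samples)
    W = np.zeros((n, n))
    donors = samples["donor"].to_numpy()
    for d in pd.unique(donors):
        idx = np.flatnonzero(donors == d)
        k = idx.size
        if k == 1 or rho == 0.0:
            W[idx, idx] = 1.0
            continue
        # eigenvalues: 1 + (k-1) rho (ones direction) and 1 - rho
        lam1 = 1.0 + (k - 1) * rho
        lam2 = 1.0 - rho
        a = 1.0 / np.sqrt(lam2)
        b = (1.0 / np.sqrt(lam1) - a) / k
        block = b * np.ones((k, k)) + a * np.eye(k)
        W[np.ix_(idx, idx)] = block
    return W


def age_group_signature(
    atlas: ExpressionAtlas,
    age_group: str,
    *,
    rho: float | None = None,
) -> pd.DataFrame:
    """Per-gene signature of one age group versus all others.

    Fits the signature model by GLS with the common intra-donor correlation
    (estimated from the atlas when not supplied) and reports the age-group +
    age-by-cortex contrast, its two-sided p-value (t with residual df), and
    the signed score sign(effect) * -log10(p).
    """
    samples = atlas.samples
    in_group = int((samples["age_group"] == age_group).sum())
    if in_group < 2 or len(samples) - in_group < 2:
        raise ValueError("need >= 2 samples inside and outside the age group")
    if rho is None:
        rho = estimate_intra_donor_rho(atlas, age_group)
    X, contrast, _ = _signature_design(samples, age_group, atlas.cortex_region)
    W = _donor_whitener(samples, rho)
    Xw = W @ X
    Yw = W @ atlas.expression.to_numpy(dtype=float).T  # samples x genes
    n, p = Xw.shape
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ Xw.T @ Yw  # p x genes
    resid = Yw - Xw @ beta
    sigma2 = (resid * resid).sum(axis=0) / (n - p)
    effect = contrast @ beta
    var_scale = float(contrast @ XtX_inv @ contrast)
    se = np.sqrt(var_scale * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    signed = np.sign(effect) * (-np.log10(pvals))
    return pd.DataFrame(
        {
            "gene": atlas.expression.index,
            "age_group": age_group,
            "effect": effect,
            "se": se,
            "p": pvals,
            "signed_score": signed,
        }
    ).set_index("gene", drop=False)


def signature_enrichment(
    twas_table: pd.DataFrame,
    signature: pd.DataFrame,
    kernel: KernelMatrix,
    *,
    two_sided: bool = True,
    min_overlap: int = 50,
) -> dict:
    """Mixed-model regression of TWAS -log10 p on the signed signature score.

    The direction of the slope is the finding (positive: MMN-associated
    genes over-expressed at that stage; negative: under-expressed), so the
    default test is two-sided.
    """
    genes = [g for g in twas_table["gene"] if g in set(signature.index) and g in set(kernel.ids)]
    if len(genes) < min_overlap:
        raise ValueError(
            f"only {len(genes)} genes shared between TWAS, signature and kernel "
            f"(need >= {min_overlap})"
        )
    tab = twas_table.set_index("gene").loc[genes]
    y = -np.log10(np.clip(tab["p"].to_numpy(dtype=float), P_FLOOR, None))
    x = signature.loc[genes, "signed_score"].to_numpy(dtype=float)
    K = kernel.subset(genes)
    X = np.column_stack([np.ones(y.size), x])
    fit = reml_fit(y, X, K)
    t, p = wald_one_sided(fit, 1, two_sided=two_sided)
    return {
        "slope": float(fit.beta[1]),
        "se": float(fit.beta_se[1]),
        "t": t,
        "p": p,
        "n_genes": len(genes),
        "age_group": signature["age_group"].iloc[0],
    }


def top_driver_genes(
    twas_table: pd.DataFrame,
    signature: pd.DataFrame,
    k: int = 10,
    *,
    slope_sign: float = 1.0,
) -> pd.DataFrame:
    """Rank-based identification of the genes driving an enrichment.

    Candidates are the overlapping genes whose signature sign is concordant
    with the enrichment slope; each is scored by the sum of its TWAS
    significance rank (most significant first) and its |signed score| rank
    (largest first), ties broken by gene id.  Returns the top k.
    """
    overlap = [g for g in twas_table["gene"] if g in set(signature.index)]
    if k > len(overlap):
        raise ValueError(f"k={k} exceeds the {len(overlap)} overlapping genes")
    tab = twas_table.set_index("gene").loc[overlap]
    sig = signature.loc[overlap]
    concordant = np.sign(sig["signed_score"]) == np.sign(slope_sign)
    pool = pd.DataFrame(
        {
            "gene": np.array(overlap)[concordant.to_numpy()],
            "twas_p": tab.loc[concordant, "p"].to_numpy(),
            "signed_score": sig.loc[concordant, "signed_score"].to_numpy(),
        }
    )
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} sign-concordant genes")
    pool["rank_twas"] = pool["twas_p"].rank(method="min")
    pool["rank_signature"] = (-pool["signed_score"].abs()).rank(method="min")
    pool["rank_sum"] = pool["rank_twas"] + pool["rank_signature"]
    pool = pool.sort_values(["rank_sum", "gene"], kind="mergesort").reset_index(drop=True)
    return pool.head(k)
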
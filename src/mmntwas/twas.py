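"""Transcriptome-wide association of MMN amplitude with meta-analysis and FDR.

Workflow per cohort and tissue: residualize the MMN amplitude on clinical
group, age, gender and lab (two-stage pre-adjustment — the per-gene model is
then a simple regression of residuals on predicted expression); associate
each gene's predicted expression with the residuals; pool cohorts by
fixed-effect inverse-variance-weighted meta-analysis; and control the false
discovery rate by Benjamini-Hochberg across the union of both tissues' gene
lists.  Unaffected relatives are recoded as healthy controls before any
analysis.  Descriptive statistics (Yates chi-square for gender by group,
pooled-variance t for age, covariate-adjusted group regressions) reproduce
the demographic reporting conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import linalg, stats

from .genotypes import GenotypeMatrix
from .grex import GrexMatrix, WeightModelSet, harmonize_alleles, impute_grex

__all__ = [
    "AssocResult",
    "recode_relatives",
    "adjust_phenotype",
    "gene_association",
    "associate_all",
    "meta_analyze",
    "bh_fdr",
    "demographic_tests",
    "pooled_t_from_summary",
    "group_effect_regressions",
    "run_twas",
]

DEFAULT_COVARIATES = ["group", "age", "gender", "lab"]
CATEGORICAL_COVARIATES = {"group", "gender", "lab", "stimulus_class"}


@dataclass
class AssocResult:
    """Single gene-phenotype association: slope in uV per expression unit."""

    gene: str
    tissue: str
    cohort: str
    beta: float
    se: float
    p: float
    ci95: tuple[float, float]
    n: int

    @classmethod
    def from_estimate(cls, gene, tissue, cohort, beta, se, p, n):
        return cls(
            gene, tissue, cohort, float(beta), float(se), float(p),
            (float(beta - 1.96 * se), float(beta + 1.96 * se)), int(n),
        )


def recode_relatives(pheno: pd.DataFrame) -> pd.DataFrame:
    """Map the 'relative' group to 'control' (unaffected relatives are
    treated as healthy controls throughout)."""
    out = pheno.copy()
    out["group"] = out["group"].replace({"relative": "control"})
    return out


def _design_matrix(pheno: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in pheno.columns:
            raise ValueError(f"covariate column {cov!r} not in phenotype table")
        if cov in CATEGORICAL_COVARIATES or pheno[cov].dtype == object:
            levels = sorted(pd.unique(pheno[cov].astype(str)))
            for level in levels[1:]:  # first level is the reference
                cols.append((pheno[cov].astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(pheno[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, names


def adjust_phenotype(
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
    *,
    column: str = "mmn_amplitude",
) -> pd.Series:
    """OLS residuals of the amplitude on the covariate design.

    Categorical covariates expand to indicator contrasts against a reference
    level; the residuals are exactly orthogonal to every design column.  A
    rank-deficient design raises, naming the aliased columns.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    pheno = recode_relatives(pheno)
    X, names = _design_matrix(pheno, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[piv[k]] for k in range(rank, X.shape[1])]
        raise ValueError(f"rank-deficient covariate design; aliased columns: {aliased}")
    y = pheno[column].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=pheno.index, name=f"{column}_adj")


def gene_association(grex_col, residuals, *, gene="", tissue="", cohort="") -> AssocResult:
    """Simple linear regression (intercept + GReX) of adjusted amplitude."""
    x = np.asarray(grex_col, dtype=float).ravel()
    y = np.asarray(residuals, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete pairs, got {n}")
    x, y = x[ok], y[ok]
    if x.std(ddof=0) == 0:
        return AssocResult(gene, tissue, cohort, np.nan, np.nan, np.nan, (np.nan, np.nan), n)
    res = stats.linregress(x, y)
    return AssocResult.from_estimate(gene, tissue, cohort, res.slope, res.stderr, res.pvalue, n)


def associate_all(grex: GrexMatrix, residuals: pd.Series, *, cohort="") -> pd.DataFrame:
    """Vectorized per-gene simple regressions; one row per gene.

    Equivalent to ``gene_association`` per column (two-sided t test on the
    slope, df = n - 2); zero-variance expression columns yield NA rows.
    """
    order = [str(s) for s in residuals.index]
    frame = grex.to_frame().loc[order]
    X = frame.to_numpy(dtype=float)
    y = residuals.to_numpy(dtype=float)
    n = y.size
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc * xc, axis=0)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.sum(yc * yc) - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1e-300)
    bad = sxx <= 0
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return pd.DataFrame(
        {
            "gene": grex.genes,
            "tissue": grex.tissue,
            "cohort": cohort,
            "beta": beta,
            "se": se,
            "p": p,
            "ci_lo": beta - 1.96 * se,
            "ci_hi": beta + 1.96 * se,
            "n": n,
        }
    )


def meta_analyze(results: list[AssocResult] | pd.DataFrame) -> dict:
    """Fixed-effect inverse-variance-weighted pooling of cohort estimates.

    Weights are 1/SE^2; the pooled SE is 1/sqrt(sum of weights) and the
    two-sided p-value comes from the normal approximation on beta/SE.
    Cohorts with NA estimates are excluded; an all-NA input yields an NA row.
    """
    if isinstance(results, pd.DataFrame):
        betas = results["beta"].to_numpy(dtype=float)
        ses = results["se"].to_numpy(dtype=float)
    else:
        betas = np.array([r.beta for r in results], dtype=float)
        ses = np.array([r.se for r in results], dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses)
    if ok.any() and np.any(ses[ok] <= 0):
        raise ValueError("standard errors must be positive")
    if not ok.any():
        return {"beta": np.nan, "se": np.nan, "p": np.nan, "n_cohorts": 0}
    w = 1.0 / ses[ok] ** 2
    beta = float(np.sum(w * betas[ok]) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))  # guard tail underflow
    return {"beta": beta, "se": se, "p": p, "n_cohorts": int(ok.sum())}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p_(i) * m / i with a cumulative minimum enforced from the largest
    rank down, capped at 1, returned in the input order.  NaN entries are
    passed through and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Two-sample pooled-variance t test from printed summary statistics."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(p)


def demographic_tests(pheno: pd.DataFrame) -> dict:
    """Demographic comparisons between patients and controls.

    Yates-continuity-corrected chi-square on the 2x2 gender-by-group table,
    pooled-variance two-sample t test for age, and group-wise summaries.
    """
    pheno = recode_relatives(pheno)
    for grp, sub in pheno.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 members")
    table = pd.crosstab(pheno["gender"], pheno["group"])
    if table.shape != (2, 2):
        raise ValueError("gender-by-group table is not 2x2")
    chi2, chi2_p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=True)
    age_pat = pheno.loc[pheno["group"] == "patient", "age"].to_numpy(dtype=float)
    age_con = pheno.loc[pheno["group"] == "control", "age"].to_numpy(dtype=float)
    t, t_p = stats.ttest_ind(age_con, age_pat, equal_var=True)
    summary = pheno.groupby("group").agg(
        n=("id", "size") if "id" in pheno.columns else ("age", "size"),
        age_mean=("age", "mean"),
        age_sd=("age", "std"),
        female_pct=("gender", lambda s: 100.0 * np.mean(s == "female")),
    )
    return {
        "n": len(pheno),
        "gender_table": table,
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "age_t": float(t),
        "age_t_p": float(t_p),
        "summary": summary,
    }


def _tidy_ols(model) -> pd.DataFrame:
    ci = model.conf_int()
    out = pd.DataFrame(
        {
            "term": model.params.index,
            "coef": model.params.to_numpy(),
            "se": model.bse.to_numpy(),
            "ci_lo": ci[0].to_numpy(),
            "ci_hi": ci[1].to_numpy(),
            "p": model.pvalues.to_numpy(),
        }
    )
    out.attrs["rsquared"] = float(model.rsquared)
    out.attrs["fvalue"] = float(model.fvalue)
    out.attrs["nobs"] = int(model.nobs)
    return out


def group_effect_regressions(pheno: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Covariate-adjusted group and stimulus-duration regressions.

    Fits amplitude ~ group + age + gender + lab on the whole sample and per
    cohort (lab dropped within a cohort, where it is single-level), plus the
    stimulus-duration models for amplitude and latency.  Factors with a
    single level are dropped with a warning.
    """
    pheno = recode_relatives(pheno).copy()

    def _formula(response: str, terms: list[str]) -> str:
        kept = []
        for t in terms:
            col = t.strip("C()")
            if col in CATEGORICAL_COVARIATES and pheno_sub[col].nunique() < 2:
                warnings.warn(f"dropping single-level factor {col!r}", UserWarning)
                continue
            kept.append(t)
        return f"{response} ~ " + " + ".join(kept)

    results: dict[str, pd.DataFrame] = {}
    pheno_sub = pheno
    results["group_whole_sample"] = _tidy_ols(
        smf.ols(
            _formula("mmn_amplitude", ["C(group)", "age", "C(gender)", "C(lab)"]),
            data=pheno_sub,
        ).fit()
    )
    for lab, sub in pheno.groupby("lab"):
        pheno_sub = sub
        if sub["group"].nunique() < 2:
            warnings.warn(f"cohort {lab!r} has a single group level; skipped", UserWarning)
            continue
        results[f"group_{lab}"] = _tidy_ols(
            smf.ols(
                _formula("mmn_amplitude", ["C(group)", "age", "C(gender)"]), data=sub
            ).fit()
        )
    pheno_sub = pheno
    results["stimulus_amplitude"] = _tidy_ols(
        smf.ols(
            _formula(
                "mmn_amplitude", ["C(stimulus_class)", "age", "C(gender)", "C(group)"]
            ),
            data=pheno_sub,
        ).fit()
    )
    results["stimulus_latency"] = _tidy_ols(
        smf.ols(
            _formula(
                "mmn_latency", ["C(stimulus_class)", "age", "C(gender)", "C(group)"]
            ),
            data=pheno_sub,
        ).fit()
    )
    return results


def run_twas(
    cohorts: dict[str, dict],
    models_by_tissue: dict[str, WeightModelSet],
    *,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Orchestrate the full TWAS and return the pooled, FDR-annotated table.

    ``cohorts`` maps cohort name -> {"genotypes": GenotypeMatrix,
    "phenotypes": DataFrame}; ``models_by_tissue`` maps tissue tag to its
    weight models.  Per cohort and tissue: residualize (lab is single-level
    within a cohort, so the default covariates there are group, age and
    gender), harmonize, impute, associate.  Genes are pooled by IVW over the
    cohorts that tested them, and BH adjustment runs once across the union
    of both tissues' meta-analyzed results.  Sorted by FDR.
    """
    if covariates is None:
        covariates = ["group", "age", "gender"]
    per_cohort = []
    for name, data in cohorts.items():
        geno: GenotypeMatrix = data["genotypes"]
        pheno: pd.DataFrame = data["phenotypes"]
        shared = [s for s in geno.samples if s in set(pheno.index.astype(str))]
        if not shared:
            warnings.warn(f"cohort {name!r} has no overlapping individuals; excluded", UserWarning)
            continue
        pheno = pheno.loc[shared]
        resid = adjust_phenotype(pheno, covariates)
        for tissue, models in models_by_tissue.items():
            harm, _ = harmonize_alleles(models.for_tissue(tissue), geno)
            if harm.table.empty:
                continue
            gx = impute_grex(geno, harm)
            keep = [i for i, s in enumerate(gx.samples) if s in set(shared)]
            gx = GrexMatrix(
                gx.values[keep], [gx.samples[i] for i in keep], gx.genes, gx.tissue, gx.usage
            )
            per_cohort.append(associate_all(gx, resid, cohort=name))
    if not per_cohort:
        raise ValueError("no cohort produced associations")
    allres = pd.concat(per_cohort, ignore_index=True)
    rows = []
    for (gene, tissue), sub in allres.groupby(["gene", "tissue"], sort=False):
        pooled = meta_analyze(sub)
        rows.append({"gene": gene, "tissue": tissue, **pooled})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("fdr", kind="mergesort").reset_index(drop=True)
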
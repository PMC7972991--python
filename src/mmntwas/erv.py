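"""Endophenotype ranking values from GREML variance components.

The endophenotype ranking value ERV = |sqrt(h_i^2) * sqrt(h_e^2) * rho_g|
indexes the genetic overlap between an illness (i) and a candidate
endophenotype (e): it is the standardized genetic covariance, bounded above
by sqrt(h_i^2 h_e^2).  The illness SNP heritability is a fixed published
input (default 0.2002 for schizophrenia at 0.4% population prevalence,
liability scale), while the endophenotype heritability and the genetic
correlation are estimated here by univariate and bivariate GREML on a
genomic relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import KernelMatrix
from .mixed_model import BivariateFit, bivariate_reml, reml_fit

__all__ = [
    "H2Estimate",
    "ErvInputs",
    "ErvResult",
    "DEFAULT_H2_ILLNESS",
    "greml_h2",
    "genetic_correlation",
    "erv",
    "rank_endophenotypes",
]

DEFAULT_H2_ILLNESS = 0.2002


@dataclass
class H2Estimate:
    """SNP heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) with a
    delta-method SE from the variance-component information matrix."""

    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    n: int
    boundary: bool = False


@dataclass
class ErvInputs:
    h2_illness: float = DEFAULT_H2_ILLNESS
    h2_endo: float = 0.0
    rho_g: float = 0.0
    h2_endo_se: float = float("nan")
    rho_g_se: float = float("nan")

    def __post_init__(self):
        for name, v in (("h2_illness", self.h2_illness), ("h2_endo", self.h2_endo)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.rho_g <= 1.0:
            raise ValueError(f"rho_g must be in [-1, 1], got {self.rho_g}")


@dataclass
class ErvResult:
    erv: float
    inputs: ErvInputs

    @property
    def upper_bound(self) -> float:
        return float(np.sqrt(self.inputs.h2_illness * self.inputs.h2_endo))


def greml_h2(y, covariates, grm: KernelMatrix, *, min_n: int = 50) -> H2Estimate:
    """Univariate GREML heritability with fixed-effect covariates.

    ``covariates`` is an (n, c) array or None; an intercept is always
    included.  The SE follows from the delta method on
    h^2 = sg2/(sg2+se2) with the numerically estimated covariance of the
    variance components.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < min_n:
        raise ValueError(f"need n >= {min_n}, got {n}")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    fit = reml_fit(y, X, grm, compute_vc_cov=True)
    sg2, se2 = fit.sigma_g2, fit.sigma_e2
    tot = sg2 + se2
    h2 = sg2 / tot if tot > 0 else 0.0
    se = float("nan")
    if fit.vc_cov is not None and tot > 0:
        grad = np.array([se2, -sg2]) / tot**2
        var = float(grad @ fit.vc_cov @ grad)
        se = float(np.sqrt(var)) if var > 0 else float("nan")
    return H2Estimate(float(h2), se, sg2, se2, n, boundary=fit.boundary)


def genetic_correlation(y1, y2, grm: KernelMatrix, *, covariates=None) -> tuple[float, float, BivariateFit]:
    """Bivariate GREML genetic correlation between two traits on one GRM.

    Returns (rho_g, SE, full fit).  Intercept-only fixed effects unless
    covariates are supplied (shared by both traits).
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    n = y1.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    fit = bivariate_reml(y1, y2, X, X, grm)
    return fit.rho_g, fit.rho_g_se, fit


def erv(inputs: ErvInputs) -> ErvResult:
    """ERV = |sqrt(h_i^2) * sqrt(h_e^2) * rho_g|."""
    value = abs(np.sqrt(inputs.h2_illness) * np.sqrt(inputs.h2_endo) * inputs.rho_g)
    return ErvResult(float(value), inputs)


def rank_endophenotypes(named_results: dict[str, ErvResult]) -> pd.DataFrame:
    """Rank candidate endophenotypes by ERV (descending; ties by name).

    The uncertainty columns report the SEs of the endophenotype heritability
    and genetic-correlation axes separately (they are not combined into a
    single ERV SE); ``overlap_note`` flags pairs of adjacent entries whose
    one-SE intervals on the ERV scale overlap.
    """
    if len(named_results) < 2:
        if len(named_results) == 1:
            name, res = next(iter(named_results.items()))
            return pd.DataFrame(
                [
                    {
                        "endophenotype": name,
                        "erv": res.erv,
                        "h2_endo": res.inputs.h2_endo,
                        "h2_endo_se": res.inputs.h2_endo_se,
                        "rho_g": res.inputs.rho_g,
                        "rho_g_se": res.inputs.rho_g_se,
                        "overlap_note": "",
                    }
                ]
            )
        raise ValueError("need at least one ErvResult to rank")
    rows = []
    for name, res in named_results.items():
        rows.append(
            {
                "endophenotype": name,
                "erv": res.erv,
                "h2_endo": res.inputs.h2_endo,
                "h2_endo_se": res.inputs.h2_endo_se,
                "rho_g": res.inputs.rho_g,
                "rho_g_se": res.inputs.rho_g_se,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["erv", "endophenotype"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    # crude one-SE ERV interval from propagating the rho_g SE alone
    half = np.abs(
        np.sqrt(np.maximum(table["h2_endo"], 0.0))
        * np.nan_to_num(table["rho_g_se"].to_numpy(), nan=0.0)
    )
    notes = [""] * len(table)
    for i in range(len(table) - 1):
        hi_next = table.loc[i + 1, "erv"] + half[i + 1]
        lo_here = table.loc[i, "erv"] - half[i]
        if hi_next > lo_here:
            notes[i] = f"uncertainty overlaps {table.loc[i + 1, 'endophenotype']}"
    table["overlap_note"] = notes
    return table
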
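"""Genetically regulated expression (GReX) imputation from SNP-weight models.

A weight model is a per-gene sparse set of (SNP, effect allele, weight)
records trained on a reference transcriptome panel, with a prediction R^2.
Predicted expression for an individual is the weighted sum of effect-allele
dosages over the model SNPs present in the genotype data:

    GReX(i, g) = sum_j w_{gj} * dosage(i, j)

Model SNPs absent from the genotypes are skipped (no reweighting), and the
per-gene usage fraction is reported so users can filter poorly covered genes.
Before imputation, allele representations are harmonized against the
genotype metadata: swapped effect/other alleles flip the weight sign,
irreconcilable allele pairs are dropped, and strand-ambiguous (A/T, C/G)
SNPs are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "WeightModelSet",
    "GrexMatrix",
    "read_weight_models",
    "write_weight_models",
    "harmonize_alleles",
    "impute_grex",
]

WEIGHT_COLUMNS = ["gene", "tissue", "rsid", "ref_allele", "eff_allele", "weight", "pred_R2", "pred_p"]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class WeightModelSet:
    """Per-gene SNP weights in long form, one row per (gene, SNP)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing required column(s): {missing}")
        dup = self.table.duplicated(subset=["gene", "rsid"])
        if dup.any():
            pair = self.table.loc[dup, ["gene", "rsid"]].iloc[0]
            raise ValueError(f"duplicate (gene, snp) row: {tuple(pair)}")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("non-finite weight encountered")
        if self.table["tissue"].isna().any():
            raise ValueError("every model row must carry a tissue tag")
        self.table = self.table.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.table["gene"]))

    def n_models(self) -> int:
        return len(self.genes)

    def for_tissue(self, tissue: str) -> "WeightModelSet":
        return WeightModelSet(self.table[self.table["tissue"] == tissue].copy())


@dataclass
class GrexMatrix:
    """Individuals x genes predicted expression plus per-gene SNP usage."""

    values: np.ndarray
    samples: list[str]
    genes: list[str]
    tissue: str
    usage: pd.DataFrame  # gene, n_used, n_model

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)


def read_weight_models(path) -> WeightModelSet:
    df = pd.read_csv(path, sep="\t")
    return WeightModelSet(df)


def write_weight_models(models: WeightModelSet, path) -> None:
    models.table.to_csv(path, sep="\t", index=False)


def harmonize_alleles(
    models: WeightModelSet,
    g: GenotypeMatrix,
    *,
    drop_ambiguous: bool = True,
) -> tuple[WeightModelSet, pd.DataFrame]:
    """Reconcile model allele coding with the genotype allele coding.

    For each model SNP found in the genotypes: matching (effect, other)
    alleles keep the weight; swapped alleles flip its sign (the imputed GReX
    then differs only by a per-gene additive constant, which downstream
    intercepts absorb); anything else is dropped.  Strand-ambiguous A/T and
    C/G SNPs are dropped unless ``drop_ambiguous=False``.  SNPs absent from
    the genotypes are retained untouched (imputation skips them).  Returns
    the harmonized set and a log of actions.
    """
    geno = g.variants.set_index("id")
    rows = []
    log = []
    for _, row in models.table.iterrows():
        rsid = row["rsid"]
        if rsid not in geno.index:
            rows.append(row)
            log.append((row["gene"], rsid, "absent_from_genotypes"))
            continue
        gv = geno.loc[rsid]
        pair = frozenset((str(row["eff_allele"]), str(row["ref_allele"])))
        if drop_ambiguous and pair in _AMBIGUOUS:
            log.append((row["gene"], rsid, "dropped_ambiguous"))
            continue
        if row["eff_allele"] == gv["effect_allele"] and row["ref_allele"] == gv["other_allele"]:
            rows.append(row)
            log.append((row["gene"], rsid, "match"))
        elif row["eff_allele"] == gv["other_allele"] and row["ref_allele"] == gv["effect_allele"]:
            flipped = row.copy()
            flipped["weight"] = -row["weight"]
            flipped["eff_allele"] = gv["effect_allele"]
            flipped["ref_allele"] = gv["other_allele"]
            rows.append(flipped)
            log.append((row["gene"], rsid, "flipped"))
        else:
            log.append((row["gene"], rsid, "dropped_mismatch"))
    out = pd.DataFrame(rows, columns=models.table.columns) if rows else models.table.iloc[:0]
    return (
        WeightModelSet(out.reset_index(drop=True)),
        pd.DataFrame(log, columns=["gene", "rsid", "action"]),
    )


def impute_grex(g: GenotypeMatrix, models: WeightModelSet) -> GrexMatrix:
    """Impute predicted expression for every model with >= 1 usable SNP.

    Missing dosage entries are mean-imputed per SNP; model SNPs absent from
    the genotype data are skipped and counted in the usage table.  Genes with
    no usable SNP are omitted (they still appear in the usage table with
    ``n_used = 0``).
    """
    tissues = pd.unique(models.table["tissue"])
    if len(tissues) > 1:
        raise ValueError(
            "impute_grex expects a single tissue; use WeightModelSet.for_tissue"
        )
    tissue = str(tissues[0]) if len(tissues) else "NA"

    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0) if d.size else np.zeros(d.shape[1])
    nan_idx = np.where(~np.isfinite(d))
    d[nan_idx] = np.take(col_mean, nan_idx[1])
    snp_pos = {snp: j for j, snp in enumerate(g.variants["id"])}

    cols = []
    genes = []
    usage = []
    for gene, sub in models.table.groupby("gene", sort=False):
        idx = [snp_pos[r] for r in sub["rsid"] if r in snp_pos]
        w = np.array([w for r, w in zip(sub["rsid"], sub["weight"]) if r in snp_pos])
        usage.append((gene, len(idx), len(sub)))
        if not idx:
            continue
        cols.append(d[:, idx] @ w)
        genes.append(gene)
    values = np.column_stack(cols) if cols else np.empty((g.n_individuals, 0))
    return GrexMatrix(
        values=values,
        samples=list(g.samples),
        genes=genes,
        tissue=tissue,
        usage=pd.DataFrame(usage, columns=["gene", "n_used", "n_model"]),
    )
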
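"""Genotype containers, threshold QC, and the genomic relationship matrix.

Dosages count copies of the effect (alternate) allele, in [0, 2], with
missing entries stored as NaN.  QC applies the usual per-SNP threshold
filters — minor allele frequency, missingness, and a 1-degree-of-freedom
chi-square goodness-of-fit test of Hardy-Weinberg equilibrium on hard-called
genotype counts — and logs every exclusion with the offending value.  The GRM
is the standardized-genotype cross-product K = ZZ'/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "KernelMatrix",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "qc_filter_snps",
    "compute_grm",
    "find_duplicates",
    "read_kernel_tsv",
    "write_kernel_tsv",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-variant metadata.

    ``dosages`` is float with NaN marking missing calls; ``variants`` has one
    row per SNP (columns ``id, chrom, pos, effect_allele, other_allele``,
    positions 1-based as in VCF); ``samples`` are the row labels.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples/variants")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages outside [0, 2]")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self) -> pd.Index:
        return pd.Index(self.variants["id"])


@dataclass
class KernelMatrix:
    """Square symmetric PSD matrix keyed by entity ids.

    ``kind`` distinguishes a GRM over individuals from an
    expression-correlation kernel over genes; ``epsilon`` records the
    eigenvalue floor applied by regularization (0 when none was needed).
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "grm"
    epsilon: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "KernelMatrix":
        pos = [self.ids.index(i) for i in keep_ids]
        idx = np.asarray(pos)
        return KernelMatrix(
            self.values[np.ix_(idx, idx)], list(keep_ids), self.kind, self.epsilon
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a dosage TSV.

    VCF GT calls are converted to alternate-allele dosage counts; ``./.``
    becomes a missing (NaN) entry.  The dosage TSV layout is one row per
    individual, header row of SNP ids, first column the sample id (allele
    metadata is then unavailable and filled with placeholder ``N`` alleles).
    """
    fmt = fmt.lower()
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt in ("tsv", "dosage", "dosage-tsv"):
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        meta = []
        for lineno, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {lineno} ({rec.id or rec.pos}) is not biallelic"
                )
            dos = np.empty(len(samples))
            for k, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    dos[k] = np.nan
                else:
                    dos[k] = sum(gt)
            rows.append(dos)
            meta.append(
                (
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    rec.chrom,
                    rec.pos,
                    rec.alts[0],  # dosage counts the alternate allele
                    rec.ref,
                )
            )
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, variants, samples)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = pd.DataFrame(
        {
            "id": df.columns,
            "chrom": "NA",
            "pos": np.arange(1, df.shape[1] + 1),
            "effect_allele": "N",
            "other_allele": "N",
        }
    )
    return GenotypeMatrix(df.to_numpy(dtype=float), variants, [str(s) for s in df.index])


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write hard-callable dosages as a minimal VCF v4.2 with GT fields.

    Non-integral dosages cannot be represented as GT calls and raise.
    """
    d = g.dosages
    finite = d[np.isfinite(d)]
    if finite.size and not np.allclose(finite, np.round(finite)):
        raise ValueError("VCF GT output requires hard-called (integer) dosages")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, row in g.variants.iterrows():
            calls = [
                "./." if not np.isfinite(d[i, j]) else gt_map[int(round(d[i, j]))]
                for i in range(g.n_individuals)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.samples, columns=g.variants["id"].to_numpy())
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_kernel_tsv(path, kind: str = "grm") -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], kind)


def write_kernel_tsv(k: KernelMatrix, path) -> None:
    df = pd.DataFrame(k.values, index=k.ids, columns=k.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_chisq(dosages: np.ndarray) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg equilibrium on
    hard-called genotype counts (missing entries ignored).  Returns (chi2, p).
    """
    d = dosages[np.isfinite(dosages)]
    g = np.round(d).astype(int)
    n = g.size
    if n == 0:
        return 0.0, 1.0
    counts = np.bincount(g, minlength=3)[:3].astype(float)
    p_hat = (2 * counts[2] + counts[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = n * np.array([q_hat**2, 2 * p_hat * q_hat, p_hat**2])
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: nothing to test
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_max: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove SNPs failing MAF, missingness, or HWE thresholds.

    A SNP failing several criteria is logged once per criterion.  Returns the
    filtered matrix and an exclusion log (``snp, criterion, value``).
    """
    for name, v in [("maf_min", maf_min), ("missing_max", missing_max), ("hwe_p_min", hwe_p_min)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    d = g.dosages
    n = d.shape[0]
    records = []
    keep = np.ones(d.shape[1], dtype=bool)
    for j, snp in enumerate(g.variants["id"]):
        col = d[:, j]
        miss = float(np.mean(~np.isfinite(col)))
        if miss > missing_max:
            records.append((snp, "missingness", miss))
            keep[j] = False
        obs = col[np.isfinite(col)]
        af = float(np.mean(obs) / 2.0) if obs.size else np.nan
        maf = min(af, 1 - af) if np.isfinite(af) else np.nan
        if not np.isfinite(maf) or maf < maf_min:
            records.append((snp, "maf", maf))
            keep[j] = False
        chi2, p_hwe = hwe_chisq(col)
        if p_hwe < hwe_p_min:
            records.append((snp, "hwe", p_hwe))
            keep[j] = False
    log = pd.DataFrame(records, columns=["snp", "criterion", "value"])
    out = GenotypeMatrix(
        d[:, keep], g.variants.loc[keep].reset_index(drop=True), list(g.samples)
    )
    if out.n_snps == 0:
        warnings.warn("QC removed every SNP", UserWarning)
    return out, log


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def compute_grm(g: GenotypeMatrix) -> KernelMatrix:
    """Genomic relationship matrix K = ZZ'/m over column-standardized dosages.

    Missing dosages are mean-imputed per SNP first; zero-variance SNPs are
    excluded with a warning.  Standardization makes K invariant to swapping
    which allele the dosage counts.
    """
    d = g.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_idx = np.where(~np.isfinite(d))
    d[nan_idx] = np.take(col_mean, nan_idx[1])
    sd = d.std(axis=0, ddof=0)
    usable = sd > 0
    if not np.all(usable):
        warnings.warn(
            f"{int(np.sum(~usable))} zero-variance SNPs excluded from GRM",
            UserWarning,
        )
    if not np.any(usable):
        raise ValueError("no SNPs with nonzero variance; cannot build GRM")
    Z = (d[:, usable] - d[:, usable].mean(axis=0)) / sd[usable]
    m = Z.shape[1]
    K = Z @ Z.T / m
    return KernelMatrix(0.5 * (K + K.T), list(g.samples), kind="grm")


def find_duplicates(k: KernelMatrix, threshold: float = 0.95) -> list[tuple[str, str, float]]:
    """Pairs with kinship above ``threshold`` — duplicate/twin candidates."""
    out = []
    v = k.values
    n = len(k.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if v[i, j] > threshold:
                out.append((k.ids[i], k.ids[j], float(v[i, j])))
    return out
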
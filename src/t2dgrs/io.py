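"""Readers and writers for genotype and summary tables.

Primary dialect: TSV with a header row of SNP ids, first column the
individual id, dosages 0/1/2 and "NA" for missing. PLINK ``.raw``
(additive recode) and VCF (GT field only) are read-only inputs; in both
cases dosages are re-expressed as risk-allele counts against the supplied
SNP metadata, flipping 2 - dosage when the counted (or ALT) allele is the
non-risk allele. Strand-ambiguous A/T and C/G variants trigger a warning
and are never strand-flipped.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def write_genotype_tsv(G: GenotypeMatrix, path) -> Path:
    path = Path(path)
    df = G.to_frame()
    # integer-format called dosages, NA for missing
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")
    return path


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix.from_frame(df)


def _risk_dosage(counted_allele: str, dosage: np.ndarray,
                 risk: str, alt: str, snp: str) -> np.ndarray:
    if is_strand_ambiguous(risk, alt):
        warnings.warn(f"{snp}: strand-ambiguous alleles {risk}/{alt}; "
                      "dosage taken at face value, no strand flip attempted")
    if counted_allele.upper() == risk.upper():
        return dosage
    if counted_allele.upper() == alt.upper():
        return 2.0 - dosage
    raise ValueError(
        f"{snp}: counted allele {counted_allele} matches neither risk "
        f"({risk}) nor alternative ({alt}) allele")


def read_plink_raw(path, snp_metadata: pd.DataFrame) -> GenotypeMatrix:
    """Read a PLINK additive-recode .raw file as risk-allele dosages.

    ``snp_metadata`` needs columns snp_id, risk_allele, alt_allele. PLINK
    column headers are '<snp_id>_<counted_allele>'.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = snp_metadata.set_index("snp_id")
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in fixed]
    snps, dosage_cols = [], []
    for col in snp_cols:
        snp, _, counted = col.rpartition("_")
        if snp not in meta.index:
            raise ValueError(f"{snp}: not present in SNP metadata")
        d = df[col].to_numpy(dtype=float)
        dosage_cols.append(_risk_dosage(counted, d, meta.at[snp, "risk_allele"],
                                        meta.at[snp, "alt_allele"], snp))
        snps.append(snp)
    return GenotypeMatrix(individuals=df["IID"].astype(str).to_numpy(), snps=snps,
                          dosage=np.column_stack(dosage_cols))


def read_vcf(path, snp_metadata: pd.DataFrame) -> GenotypeMatrix:
    """Read GT fields from a VCF as risk-allele dosages.

    ALT counts are flipped to 2 - count when the risk allele is REF.
    Records whose ID is absent from the metadata are skipped.
    """
    from cyvcf2 import VCF

    meta = snp_metadata.set_index("snp_id")
    vcf = VCF(str(path))
    individuals = np.asarray(vcf.samples)
    snps, cols = [], []
    for var in vcf:
        snp = var.ID
        if snp is None or snp not in meta.index:
            continue
        risk = str(meta.at[snp, "risk_allele"])
        alt_meta = str(meta.at[snp, "alt_allele"])
        alt = var.ALT[0] if var.ALT else alt_meta
        gts = np.array(var.genotypes, dtype=object)
        alt_count = np.array(
            [np.nan if (g[0] < 0 or g[1] < 0) else float(g[0] > 0) + float(g[1] > 0)
             for g in gts])
        if is_strand_ambiguous(risk, alt_meta):
            warnings.warn(f"{snp}: strand-ambiguous alleles {risk}/{alt_meta}; "
                          "dosage taken at face value, no strand flip attempted")
        if var.REF.upper() == risk.upper():
            d = 2.0 - alt_count
        elif alt.upper() == risk.upper():
            d = alt_count
        else:
            raise ValueError(f"{snp}: risk allele {risk} matches neither REF "
                             f"({var.REF}) nor ALT ({alt})")
        snps.append(snp)
        cols.append(d)
    vcf.close()
    return GenotypeMatrix(individuals=individuals, snps=snps,
                          dosage=np.column_stack(cols))


def read_genotypes(path, fmt: str = "tsv",
                   snp_metadata: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'tsv', 'plink_raw' or 'vcf'."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        return read_genotype_tsv(path)
    if snp_metadata is None:
        raise ValueError(f"format {fmt!r} requires SNP metadata with risk alleles")
    if fmt == "plink_raw":
        return read_plink_raw(path, snp_metadata)
    if fmt == "vcf":
        return read_vcf(path, snp_metadata)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_study_summary(path) -> pd.DataFrame:
    """Study summary TSV: snp_id plus (beta, se) or (or_, ci_low, ci_high)."""
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise ValueError("summary table must contain an snp_id column")
    has_beta = {"beta", "se"} <= set(df.columns)
    has_ci = {"or_", "ci_low", "ci_high"} <= set(df.columns)
    if not (has_beta or has_ci):
        raise ValueError("need (beta, se) or (or_, ci_low, ci_high) columns")
    if not has_beta:
        from .meta import se_from_ci

        pairs = [se_from_ci(r.or_, r.ci_low, r.ci_high) for r in df.itertuples()]
        df["beta"] = [b for b, _ in pairs]
        df["se"] = [s for _, s in pairs]
    return df
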
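"""Shared containers and numerical constants.

Dosages are risk-allele counts in {0, 1, 2}; missing entries are NaN so a
single float matrix carries both genotype and missingness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# 97.5% normal quantile at full precision: at the +/-0.01 odds-ratio
# tolerance used for printed-table comparisons, 1.96 is not close enough.
Z95 = 1.959964


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def rng_from_seed(seed) -> np.random.Generator:
    """Accept a seed or an existing Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GenotypeMatrix:
    """Rectangular individuals x SNPs risk-allele dosage matrix.

    ``dosage`` is float with entries in {0, 1, 2} and NaN for missing.
    """

    individuals: np.ndarray  # individual ids, shape (n,)
    snps: list  # SNP ids, length m
    dosage: np.ndarray = field(repr=False)  # shape (n, m)

    def __post_init__(self):
        self.individuals = np.asarray(self.individuals)
        self.snps = list(self.snps)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individuals) or m != len(self.snps):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.snps)) != m:
            raise ValueError("duplicate SNP ids")
        if len(set(self.individuals.tolist())) != n:
            raise ValueError("duplicate individual ids")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok]
            raise ValueError(f"dosages must be 0/1/2/NaN; saw {bad[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_id: str) -> int:
        return self.snps.index(snp_id)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def allele_frequency(self) -> np.ndarray:
        """Observed risk-allele frequency per SNP (missing ignored)."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            individuals=self.individuals[rows],
            snps=[self.snps[c] for c in cols],
            dosage=self.dosage[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=pd.Index(self.individuals, name="iid"),
                            columns=self.snps)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(individuals=df.index.to_numpy(), snps=list(df.columns),
                   dosage=df.to_numpy(dtype=float))
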
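"""Genotype quality control and diabetes case classification.

SNP-level QC removes variants with call rate < 95% or Hardy-Weinberg
disequilibrium at p < 0.05/384 = 1.3e-4 (1-df chi-square). Sample-level QC
removes individuals with call rate < 98% or an outlying heterozygosity
inbreeding coefficient F (robust |z| >= 5, with z computed from the median
and 1.4826*MAD because the original "SD score" leaves centre and scale
unspecified). Sex-mismatch exclusion is accepted as an input flag: no
X-chromosome intensity data are in scope.

Diabetes classification: self-reported physician diagnosis with onset
before age 30 and current insulin treatment is treated as type 1 and
excluded; other self-reports are prevalent cases; otherwise screen-detected
diabetes requires random glucose >= 7.0 mmol/l after fasting > 8 h, random
glucose >= 11.1 mmol/l with fasting < 8 h, or fasting glucose >= 7.0 mmol/l.
A fasting time of exactly 8 h satisfies neither random-glucose rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates sigma under normality


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int):
    """1-df chi-square test against Hardy-Weinberg expected counts.

    Expected counts use the estimated allele frequency; a monomorphic SNP
    returns (0.0, 1.0) rather than raising.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    p_hat = (2 * n_AA + n_Aa) / (2.0 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def snp_qc(G: GenotypeMatrix, call_threshold: float = 0.95,
           hwe_threshold: float = 1.3e-4) -> pd.DataFrame:
    """Per-SNP call-rate and HWE report with kept flags."""
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    rows = []
    call = G.snp_call_rate()
    for j, snp in enumerate(G.snps):
        d = G.dosage[:, j]
        d = d[~np.isnan(d)]
        counts = [int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())]
        if len(d):
            chi2, p = hwe_chi2_test(*counts)
        else:
            chi2, p = np.nan, np.nan
        kept = bool(call[j] >= call_threshold and (np.isnan(p) or p >= hwe_threshold))
        rows.append(dict(snp_id=snp, call_rate=float(call[j]), hwe_chi2=chi2,
                         hwe_p=p, kept=kept))
    return pd.DataFrame(rows)


def inbreeding_f(G: GenotypeMatrix) -> np.ndarray:
    """Per-sample inbreeding coefficient F = 1 - O(het)/E(het).

    Expected heterozygosity sums 2*p*(1-p) over the SNPs the sample was
    called at, with p estimated from the full matrix.
    """
    p = G.allele_frequency()
    exp_het_snp = 2.0 * p * (1.0 - p)
    called = ~np.isnan(G.dosage)
    obs_het = np.where(called & (G.dosage == 1.0), 1.0, 0.0).sum(axis=1)
    exp_het = (called * exp_het_snp[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(exp_het > 0, 1.0 - obs_het / exp_het, 0.0)


def sample_qc(G: GenotypeMatrix, call_threshold: float = 0.98,
              f_zscore_threshold: float = 5.0,
              sex_mismatch: np.ndarray | None = None) -> pd.DataFrame:
    """Per-sample call-rate and heterozygosity-F report with kept flags."""
    if G.n_individuals < 2:
        raise ValueError("need at least 2 samples")
    call = G.sample_call_rate()
    f = inbreeding_f(G)
    med = np.median(f)
    mad = np.median(np.abs(f - med)) * MAD_SCALE
    if mad == 0:
        z = np.zeros_like(f)
    else:
        z = (f - med) / mad
    kept = (call >= call_threshold) & (np.abs(z) < f_zscore_threshold)
    if sex_mismatch is not None:
        kept &= ~np.asarray(sex_mismatch, dtype=bool)
    if not kept.any():
        raise ValueError("sample QC removed every sample")
    return pd.DataFrame(dict(iid=G.individuals, call_rate=call, het_f=f,
                             f_zscore=z, kept=kept))


@dataclass
class PhenotypeRecord:
    self_report_diabetes: bool = False
    age_at_onset: float | None = None
    insulin_treated: bool = False
    random_glucose: float | None = None
    fasting_glucose: float | None = None
    fasting_time: float | None = None

    def __post_init__(self):
        for name in ("random_glucose", "fasting_glucose"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


def classify_diabetes_status(r: PhenotypeRecord) -> str:
    """Classify one participant into control / prevalent_selfreport /
    screen_detected / type1_excluded."""
    has_glucose = r.random_glucose is not None or r.fasting_glucose is not None
    if not r.self_report_diabetes and not has_glucose:
        raise ValueError("no self-report and no glucose measurement")
    if r.self_report_diabetes:
        if (r.age_at_onset is not None and r.age_at_onset < 30 and r.insulin_treated):
            return "type1_excluded"
        return "prevalent_selfreport"
    if r.random_glucose is not None and r.fasting_time is not None:
        if r.random_glucose >= 7.0 and r.fasting_time > 8.0:
            return "screen_detected"
        if r.random_glucose >= 11.1 and r.fasting_time < 8.0:
            return "screen_detected"
    if r.fasting_glucose is not None and r.fasting_glucose >= 7.0:
        return "screen_detected"
    return "control"
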
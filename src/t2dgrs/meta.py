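"""Inverse-variance fixed-effect meta-analysis with heterogeneity.

Study inputs are per-SNP log odds ratios with standard errors; when only a
printed odds ratio and 95% CI are available the standard error is recovered
as (ln hi - ln lo) / (2 * 1.959964). Pooling uses weights w = 1/se^2:
beta_pooled = sum(w*b)/sum(w), se_pooled = 1/sqrt(sum(w)). Between-study
heterogeneity is Cochran's Q = sum(w*(b - b_pooled)^2), chi-square with
k-1 df under homogeneity; the default significance threshold for
heterogeneity screens is the Bonferroni value 0.05/(55*3) = 3.0e-4.
"""
from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import Z95

HETEROGENEITY_ALPHA = 0.05 / (55 * 3)  # Bonferroni across 55 SNPs x 3 contrasts


@dataclass
class StudyEstimate:
    study: str
    snp_id: str
    beta: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.study}/{self.snp_id}: se must be > 0")


@dataclass
class MetaResult:
    snp_id: str
    beta_pooled: float
    se_pooled: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    Q: float
    df: int
    p_het: float


def se_from_ci(or_: float, lo: float, hi: float, level: float = 0.95):
    """Recover (beta, se) from a printed odds ratio and CI."""
    if not (0 < lo <= or_ <= hi):
        raise ValueError(f"require 0 < lo <= or <= hi, got ({or_}, {lo}, {hi})")
    if lo == hi:
        raise ValueError("zero-width confidence interval")
    z = stats.norm.ppf(0.5 + level / 2.0) if level != 0.95 else Z95
    return math.log(or_), (math.log(hi) - math.log(lo)) / (2.0 * z)


def ivw_fixed_meta(estimates: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of one SNP's study estimates."""
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    snp_ids = {e.snp_id for e in estimates}
    if len(snp_ids) > 1:
        raise ValueError(f"estimates span multiple SNPs: {sorted(snp_ids)}")
    b = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    if len(estimates) >= 2:
        Q = float(np.sum(w * (b - beta) ** 2))
        df = len(estimates) - 1
        p_het = float(stats.chi2.sf(Q, df))
    else:
        Q, df, p_het = 0.0, 0, 1.0
    return MetaResult(snp_id=estimates[0].snp_id, beta_pooled=beta, se_pooled=se,
                      or_=math.exp(beta), ci_low=math.exp(beta - Z95 * se),
                      ci_high=math.exp(beta + Z95 * se), p=p, Q=Q, df=df, p_het=p_het)


def cochran_q(estimates: list[StudyEstimate]):
    """(Q, df, p_het) for a set of study estimates of one SNP."""
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least 2 estimates")
    res = ivw_fixed_meta(estimates)
    return res.Q, res.df, res.p_het


def pool_summary_frame(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool several studies' per-SNP summary tables.

    Each frame needs columns ``snp_id`` and either (beta, se) or
    (or_, ci_low, ci_high). SNPs present in only one study are pooled
    trivially (df = 0).
    """
    estimates: dict[str, list[StudyEstimate]] = {}
    for study, df in frames.items():
        for row in df.itertuples():
            if hasattr(row, "beta") and hasattr(row, "se") and not (
                    pd.isna(row.beta) or pd.isna(row.se)):
                b, s = float(row.beta), float(row.se)
            else:
                if pd.isna(row.or_):
                    continue
                b, s = se_from_ci(float(row.or_), float(row.ci_low), float(row.ci_high))
            estimates.setdefault(row.snp_id, []).append(
                StudyEstimate(study=study, snp_id=row.snp_id, beta=b, se=s))
    rows = []
    for snp_id, ests in estimates.items():
        r = ivw_fixed_meta(ests)
        rows.append(dict(snp_id=snp_id, n_studies=len(ests), beta=r.beta_pooled,
                         se=r.se_pooled, or_=r.or_, ci_low=r.ci_low,
                         ci_high=r.ci_high, p=r.p, Q=r.Q, df=r.df, p_het=r.p_het))
    return pd.DataFrame(rows)
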
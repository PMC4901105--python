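"""Effect-size attenuation between discovery-style and population estimates.

The headline statistic is the slope of a weighted least-squares regression
through the origin of population (cohort) log odds ratios y on reference
(discovery) log odds ratios x, weighted by the inverse variance of y:

    slope = sum(w x y) / sum(w x^2),  w = 1/se_y^2,
    se(slope) = 1 / sqrt(sum(w x^2)).

The proportional reduction is 1 - slope; selection of discovery estimates
at a significance threshold (winner's curse) and extreme-phenotype sampling
(spectrum bias) both push the slope below 1. Reference-estimate uncertainty
is deliberately ignored (the weights use only the cohort variance); a
bivariate errors-in-variables treatment is out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Z95


@dataclass
class EffectPair:
    snp_id: str
    x: float  # reference (discovery) log-OR
    y: float  # target (population cohort) log-OR
    y_se: float

    def __post_init__(self):
        if not self.y_se > 0:
            raise ValueError(f"{self.snp_id}: y_se must be > 0")


@dataclass
class ShrinkageResult:
    slope: float
    slope_se: float
    reduction: float  # 1 - slope, proportional attenuation
    reduction_ci_low: float
    reduction_ci_high: float
    p_vs_unity: float
    r: float | None  # Pearson correlation of effect sizes
    n_pairs: int


def through_origin_wls(pairs: list[EffectPair]) -> ShrinkageResult:
    """Inverse-variance weighted regression through the origin."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    x = np.array([p.x for p in pairs])
    y = np.array([p.y for p in pairs])
    w = np.array([1.0 / p.y_se**2 for p in pairs])
    sxx = np.sum(w * x * x)
    if sxx == 0:
        raise ValueError("all reference effects are zero")
    slope = float(np.sum(w * x * y) / sxx)
    se = float(1.0 / np.sqrt(sxx))
    z = (1.0 - slope) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    r = effect_correlation(pairs) if len(pairs) >= 3 else None
    return ShrinkageResult(
        slope=slope, slope_se=se, reduction=1.0 - slope,
        reduction_ci_low=1.0 - (slope + Z95 * se),
        reduction_ci_high=1.0 - (slope - Z95 * se),
        p_vs_unity=p, r=r, n_pairs=len(pairs))


def effect_correlation(pairs: list[EffectPair]) -> float:
    """Pearson correlation of reference and target effect sizes."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p.x for p in pairs])
    y = np.array([p.y for p in pairs])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in effect sizes")
    return float(np.corrcoef(x, y)[0, 1])
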
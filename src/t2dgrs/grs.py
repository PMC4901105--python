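"""Genetic risk scores: construction, rescaling, mechanism classes,
variance explained and quartile analysis with floating absolute risks.

A weighted GRS is sum_i w_i g_i over a named SNP subset, with weights the
natural log of per-allele odds ratios from a chosen source (or all 1 for
the unweighted score). Weighted scores are rescaled so that one point
corresponds on average to one risk allele:

    GRS' = GRS * (2 M) / (2 sum w) = GRS * M / sum(w),

where 2M — twice the number of SNPs in the score — is the maximal
risk-allele count. With equal weights the rescaled score equals the plain
risk-allele count exactly, and any linear rescaling leaves association
z-statistics unchanged.

Missing genotypes are imputed with the mean observed dosage of the SNP
within the individual's regional centre (falling back to the overall mean
for centres with no observations).

Quartile associations report floating absolute risks: every quartile,
including the reference, is assigned a floated variance such that the
variance of any pairwise log-OR contrast is approximated by the sum of the
two floated variances (quasi-variances; exact for two levels).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .core import GenotypeMatrix, Z95

BC_CRITERIA = ("homa_b_decreased", "ogtt_bc_index", "bc_cluster", "monogenic_locus")
IR_CRITERIA = ("homa_ir_increased", "fasting_insulin_up", "ir_cluster",
               "triacylglycerol_ir_trait")


@dataclass
class WeightScheme:
    """Named mapping snp_id -> per-allele log-OR weight."""

    label: str
    weights: dict[str, float]
    unweighted: bool = False

    def __post_init__(self):
        vals = np.array(list(self.weights.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.label}: weights must be finite")
        if self.unweighted and not np.allclose(vals, 1.0):
            raise ValueError("unweighted scheme requires all weights == 1")

    @classmethod
    def unweighted_for(cls, snp_ids) -> "WeightScheme":
        return cls(label="unweighted", weights={s: 1.0 for s in snp_ids},
                   unweighted=True)


@dataclass
class GrsDefinition:
    """A named score: SNP subset plus weight scheme (overall / BC / IR)."""

    name: str
    snp_ids: list[str]
    scheme: WeightScheme

    def __post_init__(self):
        if len(self.snp_ids) == 0:
            raise ValueError("empty SNP subset")
        missing = [s for s in self.snp_ids if s not in self.scheme.weights]
        if missing:
            raise ValueError(f"SNPs missing from scheme {self.scheme.label}: {missing}")


@dataclass
class EvidenceRecord:
    """Per-SNP mechanism evidence flags (beta-cell vs insulin resistance)."""

    snp_id: str
    homa_b_decreased: bool = False
    ogtt_bc_index: bool = False
    bc_cluster: bool = False
    monogenic_locus: bool = False
    homa_ir_increased: bool = False
    fasting_insulin_up: bool = False
    ir_cluster: bool = False
    triacylglycerol_ir_trait: bool = False
    obesity_mediated: bool = False


@dataclass
class GrsProfile:
    """Per-individual raw and rescaled scores for one definition."""

    name: str
    individuals: np.ndarray
    raw: np.ndarray
    rescaled: np.ndarray
    n_imputed: np.ndarray
    scheme_label: str
    snp_ids: list[str] = field(default_factory=list)


def impute_missing_by_centre_mean(G: GenotypeMatrix, centre) -> GenotypeMatrix:
    """Replace missing dosages by the SNP's mean observed dosage within the
    individual's centre; fall back to the overall mean for empty centres."""
    centre = np.asarray(centre)
    if len(centre) != G.n_individuals:
        raise ValueError("centre labels do not align with genotype rows")
    dos = G.dosage.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        overall = np.nanmean(dos, axis=0)
    if np.isnan(overall).any():
        bad = [G.snps[j] for j in np.flatnonzero(np.isnan(overall))]
        raise ValueError(f"SNPs with no observed genotypes anywhere: {bad}")
    for c in np.unique(centre):
        rows = centre == c
        block = dos[rows]
        cmean = np.array([
            np.nanmean(block[:, j]) if not np.isnan(block[:, j]).all() else np.nan
            for j in range(block.shape[1])])
        empty = np.isnan(cmean)
        if empty.any():
            warnings.warn(
                f"centre {c!r}: no observed genotypes for "
                f"{[G.snps[j] for j in np.flatnonzero(empty)]}; using overall mean")
            cmean = np.where(empty, overall, cmean)
        miss = np.isnan(block)
        block[miss] = np.broadcast_to(cmean, block.shape)[miss]
        dos[rows] = block
    out = GenotypeMatrix.__new__(GenotypeMatrix)  # bypass 0/1/2 check: imputed means
    out.individuals = G.individuals.copy()
    out.snps = list(G.snps)
    out.dosage = dos
    return out


def compute_grs(G: GenotypeMatrix, definition: GrsDefinition,
                imputed_mask: np.ndarray | None = None) -> GrsProfile:
    """Raw and rescaled weighted risk scores for one definition."""
    idx = [G.snp_index(s) for s in definition.snp_ids]
    dos = G.dosage[:, idx]
    if np.isnan(dos).any():
        raise ValueError("missing dosages: impute before scoring")
    w = np.array([definition.scheme.weights[s] for s in definition.snp_ids])
    sum_w = w.sum()
    if sum_w <= 0:
        raise ValueError("sum of weights must be positive")
    raw = dos @ w
    m = len(definition.snp_ids)
    rescaled = raw * (2.0 * m) / (2.0 * sum_w)
    if imputed_mask is not None:
        n_imp = np.asarray(imputed_mask, dtype=bool)[:, idx].sum(axis=1)
    else:
        n_imp = np.zeros(G.n_individuals, dtype=int)
    return GrsProfile(name=definition.name, individuals=G.individuals.copy(),
                      raw=raw, rescaled=rescaled, n_imputed=n_imp,
                      scheme_label=definition.scheme.label,
                      snp_ids=list(definition.snp_ids))


def classify_mechanism(e: EvidenceRecord, bc_precedence: bool = True) -> str:
    """'BC' if any beta-cell criterion holds; else 'IR' if any insulin-
    resistance criterion holds and the locus does not act primarily through
    obesity; else 'unclassified'. BC takes precedence on conflicting
    evidence (configurable)."""
    bc = any(getattr(e, f) for f in BC_CRITERIA)
    ir = any(getattr(e, f) for f in IR_CRITERIA) and not e.obesity_mediated
    if bc and ir:
        return "BC" if bc_precedence else "IR"
    if bc:
        return "BC"
    if ir:
        return "IR"
    return "unclassified"


def variance_explained(beta: float, se: float, raf: float, n: int) -> float:
    """Plug-in proportion of phenotype variance explained by one SNP:

    PVE = 2 b^2 p(1-p) / (2 b^2 p(1-p) + se^2 * 2 n * p(1-p)).
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0.0 < raf < 1.0:
        raise ValueError("raf must lie strictly inside (0,1)")
    num = 2.0 * beta**2 * raf * (1.0 - raf)
    return num / (num + se**2 * 2.0 * n * raf * (1.0 - raf))


def quantile_bins(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Sample-quantile bins 0..n_bins-1 with boundary ties assigned to the
    lower bin."""
    values = np.asarray(values, dtype=float)
    cuts = np.quantile(values, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(cuts, values, side="left")


def floated_variances(cov: np.ndarray) -> np.ndarray:
    """Quasi-variances for a categorical exposure with reference level.

    ``cov`` is the (k-1)x(k-1) covariance of the non-reference log-OR
    coefficients. Returns k floated variances (reference first) minimising
    the summed squared relative error of all pairwise contrast variances;
    exact when k = 2.
    """
    k1 = cov.shape[0]
    pairs, targets = [], []
    for j in range(k1):  # contrasts against the reference
        pairs.append((0, j + 1))
        targets.append(cov[j, j])
    for i in range(k1):
        for j in range(i + 1, k1):
            pairs.append((i + 1, j + 1))
            targets.append(cov[i, i] + cov[j, j] - 2.0 * cov[i, j])
    targets = np.asarray(targets)
    if np.any(targets <= 0):
        raise ValueError("non-positive contrast variance")
    if k1 == 1:  # two levels: split the single contrast variance exactly
        return np.full(2, targets[0] / 2.0)

    def resid(log_v):
        v = np.exp(log_v)
        s = np.array([v[i] + v[j] for i, j in pairs])
        return s / targets - 1.0

    x0 = np.log(np.full(k1 + 1, max(targets.mean() / 2.0, 1e-12)))
    sol = optimize.least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return np.exp(sol.x)


def quartile_association(score, y, covariates=None, n_bins: int = 4) -> pd.DataFrame:
    """Per-quartile ORs (lowest quartile = reference) with floated 95% CIs.

    The logistic model codes quartile indicators plus covariates; floated
    variances give every level, including the reference, its own CI such
    that any pairwise contrast variance is approximated by the sum of the
    two floated variances.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y)
    if len(np.unique(score)) < n_bins:
        raise ValueError("score has fewer distinct values than bins")
    bins = quantile_bins(score, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError("empty quantile bin")
    X = pd.get_dummies(pd.Series(bins, name="q"), prefix="q", drop_first=True,
                       dtype=float)
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.GLM(y, X.astype(float), family=sm.families.Binomial()).fit()
    qcols = [c for c in X.columns if c.startswith("q_")]
    beta = np.concatenate([[0.0], fit.params[qcols].to_numpy()])
    cov = fit.cov_params().loc[qcols, qcols].to_numpy()
    fv = floated_variances(cov)
    fse = np.sqrt(fv)
    rows = []
    for lev in range(n_bins):
        n_case = int(((bins == lev) & (y == 1)).sum())
        n_ctrl = int(((bins == lev) & (y == 0)).sum())
        wald_p = (np.nan if lev == 0 else
                  float(2.0 * stats.norm.sf(abs(beta[lev]) /
                                            np.sqrt(cov[lev - 1, lev - 1]))))
        rows.append(dict(
            quartile=lev + 1, n_cases=n_case, n_controls=n_ctrl,
            log_or=float(beta[lev]), or_=float(np.exp(beta[lev])),
            float_var=float(fv[lev]),
            ci_low=float(np.exp(beta[lev] - Z95 * fse[lev])),
            ci_high=float(np.exp(beta[lev] + Z95 * fse[lev])),
            p=wald_p))
    return pd.DataFrame(rows)
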
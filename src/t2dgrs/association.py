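"""Per-SNP case-control association and multiplicity control.

The per-allele model is plain maximum-likelihood logistic regression of
case status on risk-allele dosage, adjusted for age, sex and regional
centre (centre entered as indicator terms). Wald standard errors and 95%
confidence intervals use z = 1.959964. Covariate-free fits are collapsed to
the 3 x 2 dosage-by-outcome count table and solved by Newton iteration,
which gives the identical MLE at a fraction of the cost — this is the path
the simulation loops use.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import Z95, rng_from_seed, sigmoid

CHI2_1_MEDIAN = 0.4549364  # median of the 1-df chi-square distribution


@dataclass
class AssocResult:
    snp_id: str | None
    n_used: int
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    raf_observed: float
    flag: str | None = None  # 'separation', 'non_convergence', 'monomorphic'

    def to_dict(self) -> dict:
        return dict(snp_id=self.snp_id, n_used=self.n_used, beta=self.beta,
                    se=self.se, or_=self.or_, ci_low=self.ci_low,
                    ci_high=self.ci_high, p=self.p,
                    raf_observed=self.raf_observed, flag=self.flag)


@dataclass
class InflationResult:
    lambda_obs: float
    lambda_1000: float
    n_cases: int
    n_controls: int
    n_snps_used: int


def fit_counts_logistic(case_counts, ctrl_counts, max_iter: int = 50,
                        tol: float = 1e-10):
    """Newton MLE of logit P(case) = a + b*g on collapsed genotype counts.

    ``case_counts``/``ctrl_counts`` are length-3 arrays of genotype counts
    (g = 0, 1, 2). Returns (beta, se, p, flag).
    """
    n1 = np.asarray(case_counts, dtype=float)
    n0 = np.asarray(ctrl_counts, dtype=float)
    if n1.sum() == 0 or n0.sum() == 0:
        raise ValueError("need at least one case and one control")
    g = np.array([0.0, 1.0, 2.0])
    tot = n1 + n0
    present = tot > 0
    # monomorphic or single observed genotype: slope not identifiable
    if present.sum() < 2:
        return 0.0, np.inf, 1.0, "monomorphic"
    # separation: cases and controls occupy disjoint genotype sets
    if not np.any((n1 > 0) & (n0 > 0)):
        return np.nan, np.inf, np.nan, "separation"
    X = np.column_stack([np.ones(3), g])
    theta = np.zeros(2)
    flag = None
    for _ in range(max_iter):
        p = sigmoid(X @ theta)
        grad = X.T @ (n1 - tot * p)
        w = tot * p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.nan, np.inf, np.nan, "separation"
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        flag = "non_convergence"
    if np.max(np.abs(theta)) > 30:
        return theta[1], np.inf, np.nan, "separation"
    p = sigmoid(X @ theta)
    w = tot * p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    beta = theta[1]
    se = float(np.sqrt(cov[1, 1]))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(beta), se, float(pval), flag


def build_covariates(age=None, is_female=None, centre=None, extra=None) -> pd.DataFrame:
    """Standard adjustment set: age, sex and centre indicator columns."""
    cols = {}
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
    if is_female is not None:
        cols["is_female"] = np.asarray(is_female, dtype=float)
    df = pd.DataFrame(cols)
    if centre is not None:
        dummies = pd.get_dummies(pd.Series(np.asarray(centre), name="centre"),
                                 prefix="centre", drop_first=True, dtype=float)
        df = pd.concat([df.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    if extra is not None:
        extra = pd.DataFrame(extra).reset_index(drop=True)
        df = pd.concat([df, extra], axis=1)
    return df


def fit_snp_logistic(dosage, y, covariates=None, snp_id=None) -> AssocResult:
    """Covariate-adjusted per-allele logistic association for one SNP.

    Missing dosages must be imputed or dropped upstream. Non-convergence or
    separation is reported through ``flag`` rather than raising.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y)
    if np.isnan(dosage).any():
        raise ValueError("missing dosages: impute or drop before fitting")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary 0/1")
    n = len(dosage)
    raf_obs = float(dosage.mean() / 2.0)

    def _result(beta, se, p, flag):
        if np.isfinite(se):
            lo, hi = beta - Z95 * se, beta + Z95 * se
        else:
            lo, hi = -np.inf, np.inf
        with np.errstate(over="ignore"):
            return AssocResult(snp_id=snp_id, n_used=n, beta=beta, se=se,
                               or_=float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                               ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
                               p=p, raf_observed=raf_obs, flag=flag)

    if covariates is None and np.isin(dosage, (0.0, 1.0, 2.0)).all():
        n1 = np.array([np.sum((dosage == g) & (y == 1)) for g in (0, 1, 2)])
        n0 = np.array([np.sum((dosage == g) & (y == 0)) for g in (0, 1, 2)])
        beta, se, p, flag = fit_counts_logistic(n1, n0)
        return _result(beta, se, p, flag)

    X = pd.DataFrame({"dosage": dosage})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.GLM(y, X.astype(float), family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return _result(np.nan, np.inf, np.nan, "separation")
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    flag = None
    if not fit.converged:
        flag = "non_convergence"
    elif se > 50 or abs(beta) > 30:
        flag = "separation"
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
    return _result(beta, se, p, flag)


def association_scan(G, y, covariates=None, impute_dosage=None) -> pd.DataFrame:
    """fit_snp_logistic over every SNP of a genotype matrix."""
    rows = []
    for j, snp in enumerate(G.snps):
        d = G.dosage[:, j]
        if np.isnan(d).any():
            if impute_dosage is None:
                keep = ~np.isnan(d)
                res = fit_snp_logistic(
                    d[keep], np.asarray(y)[keep],
                    None if covariates is None else pd.DataFrame(covariates).iloc[keep],
                    snp_id=snp)
                rows.append(res.to_dict())
                continue
            d = impute_dosage[:, j]
        res = fit_snp_logistic(d, y, covariates, snp_id=snp)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def sign_concordance_test(signs_observed, signs_reference):
    """Exact one-sided binomial sign test of directional concordance.

    Returns (k_concordant, n, p) with p = P(X >= k | n, 1/2). The one-sided
    tail is used because it reproduces the published concordance p-values.
    """
    a = np.sign(np.asarray(signs_observed, dtype=float))
    b = np.sign(np.asarray(signs_reference, dtype=float))
    if len(a) != len(b):
        raise ValueError("sign vectors differ in length")
    if len(a) == 0:
        raise ValueError("empty sign vectors")
    if np.any(a == 0) or np.any(b == 0):
        raise ValueError("zero signs are not allowed")
    k = int(np.sum(a == b))
    n = len(a)
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return k, n, p


def genomic_inflation(chi2_stats, n_cases: int, n_controls: int) -> InflationResult:
    """Genomic-control lambda and its rescaling to 1,000 cases + controls.

    lambda_obs = median(chi2) / 0.4549364;
    lambda_1000 = 1 + (lambda_obs - 1) * (1/n_cases + 1/n_controls) / (2/1000).
    """
    x = np.asarray(chi2_stats, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 statistics")
    if np.any(x < 0):
        raise ValueError("chi-square statistics must be non-negative")
    lam = float(np.median(x) / CHI2_1_MEDIAN)
    lam1000 = 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
    return InflationResult(lambda_obs=lam, lambda_1000=lam1000, n_cases=n_cases,
                           n_controls=n_controls, n_snps_used=len(x))


def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Holm (step-down FWER) or Benjamini-Hochberg (step-up FDR) adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter=50, tol=1e-9) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = sigmoid(X @ beta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _score_z(dosages: np.ndarray, y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Rao score z per SNP under the covariate-only null model."""
    beta0 = _irls_logistic(C, y)
    p0 = sigmoid(C @ beta0)
    w = p0 * (1.0 - p0)
    # residualise each dosage column against covariates in the W metric
    CtWC = (C * w[:, None]).T @ C
    CtWX = (C * w[:, None]).T @ dosages
    Xres = dosages - C @ np.linalg.solve(CtWC, CtWX)
    U = Xres.T @ (y - p0)
    V = np.einsum("ij,i,ij->j", Xres, w, Xres)
    with np.errstate(invalid="ignore", divide="ignore"):
        return U / np.sqrt(V)


def permutation_fwer(dosages, y, covariates=None, n_perm: int = 1000, seed=0) -> np.ndarray:
    """Family-wise-error adjusted p-values by max-|z| phenotype permutation.

    The phenotype is permuted against the (dosage, covariate) rows; each
    permutation refits the covariate-only null and recomputes score z
    statistics, and the observed |z| of each SNP is referred to the null
    distribution of the permutation maxima:
    p_adj = (1 + #{perm max >= |z_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = np.asarray(dosages, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate phenotype")
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = sm.add_constant(pd.DataFrame(covariates).astype(float),
                            has_constant="add").to_numpy()
    rng = rng_from_seed(seed)
    z_obs = np.abs(_score_z(X, y, C))
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        max_null[b] = np.nanmax(np.abs(_score_z(X, yp, C)))
    exceed = (max_null[:, None] >= z_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)
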
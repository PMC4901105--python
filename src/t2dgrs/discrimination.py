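"""ROC discrimination of risk scores and paired score comparison.

The C-statistic is P(score_case > score_control) + 1/2 P(tie) over all
case-control pairs, computed with the midrank formula. Variances come from
the DeLong structural-components estimator: with cases i and controls j,

    V10_i = mean_j [I(x_i > y_j) + 1/2 I(x_i = y_j)],
    V01_j = mean_i [I(x_i > y_j) + 1/2 I(x_i = y_j)],
    var(C) = var(V10)/m + var(V01)/n.

The paired DeLong test for two scores on the same individuals uses the
2x2 covariance of the components; ties count 1/2 throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import Z95


@dataclass
class RocResult:
    c_statistic: float
    ci_low: float
    ci_high: float
    se: float
    n_cases: int
    n_controls: int


@dataclass
class DelongComparison:
    delta_c: float
    se_delta: float
    p: float
    c_a: float
    c_b: float


def _components(scores: np.ndarray, y: np.ndarray):
    """(auc, V10 per case, V01 per control) via midranks."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    allv = np.concatenate([pos, neg])
    r_all = stats.rankdata(allv)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def c_statistic(scores, y) -> RocResult:
    """C-statistic with a DeLong-variance 95% CI (clipped to [0,1])."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    auc, v10, v01 = _components(scores, y)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    return RocResult(c_statistic=auc,
                     ci_low=float(max(0.0, auc - Z95 * se)),
                     ci_high=float(min(1.0, auc + Z95 * se)),
                     se=se, n_cases=m, n_controls=n)


def delong_test(scores_a, scores_b, y) -> DelongComparison:
    """Paired DeLong comparison of two scores over the same individuals."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("scores and labels must have equal length")
    auc_a, v10_a, v01_a = _components(a, y)
    auc_b, v10_b, v01_b = _components(b, y)
    m, n = len(v10_a), len(v01_a)
    delta = auc_a - auc_b
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / se))
    return DelongComparison(delta_c=float(delta), se_delta=se, p=p,
                            c_a=auc_a, c_b=auc_b)


def roc_curve_points(scores, y) -> pd.DataFrame:
    """(threshold, fpr, tpr) table for plotting, descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    return pd.DataFrame({
        "threshold": scores[order],
        "tpr": tp / max(1, (y == 1).sum()),
        "fpr": fp / max(1, (y == 0).sum()),
    })


def make_folds(n: int, k_folds: int, seed=0) -> np.ndarray:
    """Fold labels 0..k-1 by a seeded permutation, sizes differing by <= 1."""
    from .core import rng_from_seed

    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rng = rng_from_seed(seed)
    labels = np.arange(n) % k_folds
    return labels[rng.permutation(n)]


def crossvalidate_weights(G, y, covariates, external: pd.DataFrame,
                          k_folds: int, seed=0, use_covariates: bool = True):
    """Leave-fold-out cross-validated combined-weight discrimination.

    For each fold the per-SNP cohort log-ORs are refitted on the complement,
    pooled with the external estimates by inverse-variance fixed-effect
    meta-analysis, and the resulting weights are applied only to the
    held-out individuals. ``external`` needs columns snp_id, beta, se.
    Returns (out-of-fold scores aligned to rows, RocResult).

    The motivating design excluded random 0.1% subsets, i.e. k = 1000 folds;
    k is a parameter so tests can run at modest fold counts.
    """
    from .association import fit_snp_logistic
    from .meta import StudyEstimate, ivw_fixed_meta

    y = np.asarray(y)
    n = G.n_individuals
    if np.isnan(G.dosage).any():
        raise ValueError("impute missing dosages before cross-validation")
    ext = {r.snp_id: (float(r.beta), float(r.se)) for r in external.itertuples()}
    folds = make_folds(n, k_folds, seed)
    oof = np.full(n, np.nan)
    cov_df = None if covariates is None else pd.DataFrame(covariates).reset_index(drop=True)
    for f in range(k_folds):
        hold = folds == f
        train = ~hold
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f}: single-class training complement; skipped")
            continue
        weights = {}
        for j, snp in enumerate(G.snps):
            d = G.dosage[train, j]
            res = fit_snp_logistic(
                d, y[train],
                cov_df.iloc[train] if (use_covariates and cov_df is not None) else None,
                snp_id=snp)
            ests = []
            if res.flag is None and np.isfinite(res.se):
                ests.append(StudyEstimate("cohort", snp, res.beta, res.se))
            if snp in ext:
                ests.append(StudyEstimate("external", snp, *ext[snp]))
            if not ests:
                continue
            weights[snp] = ivw_fixed_meta(ests).beta_pooled
        cols = [G.snp_index(s) for s in weights]
        w = np.array([weights[s] for s in weights])
        oof[hold] = G.dosage[np.ix_(np.flatnonzero(hold), cols)] @ w
    used = ~np.isnan(oof)
    roc = c_statistic(oof[used], y[used])
    return oof, roc
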
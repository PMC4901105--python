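"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^2) pair enumeration, grid
search, exhaustive step-down — and shares no code with the library paths
it checks.
"""
from __future__ import annotations

import itertools

import numpy as np


def auc_by_enumeration(scores, y):
    """C-statistic by explicit loop over all case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_components_by_enumeration(scores, y):
    """(auc, V10 per case, V01 per control) by pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)


def delong_paired_variance_by_enumeration(a, b, y):
    """(delta_auc, variance) for two paired scores, from raw components."""
    auc_a, v10a, v01a = delong_components_by_enumeration(a, y)
    auc_b, v10b, v01b = delong_components_by_enumeration(b, y)
    m, n = len(v10a), len(v01a)
    var = 0.0
    if m > 1:
        s = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s[0, 0] + s[1, 1] - 2 * s[0, 1]) / m
    if n > 1:
        s = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s[0, 0] + s[1, 1] - 2 * s[0, 1]) / n
    return auc_a - auc_b, var


def holm_by_brute_force(p):
    """Step-down Holm adjustment computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (n - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj

def bh_by_brute_force(p):
    """Step-up Benjamini-Hochberg adjustment from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, n * p[idx] / (rank + 1))
        adj[idx] = min(1.0, running)
    return adj


def logistic_loglik_counts(a, b, case_counts, ctrl_counts):
    g = np.array([0.0, 1.0, 2.0])
    eta = a + b * g
    # log-likelihood of collapsed dosage x outcome table
    return float(np.sum(case_counts * eta - (case_counts + ctrl_counts) *
                        np.log1p(np.exp(eta))))


def logistic_mle_by_grid(case_counts, ctrl_counts, b_range=(-2.0, 2.0)):
    """Slope MLE by nested grid search on the collapsed count table."""
    best = None
    a_lo, a_hi = -8.0, 2.0
    b_lo, b_hi = b_range
    for _ in range(8):  # successive refinement
        a_grid = np.linspace(a_lo, a_hi, 41)
        b_grid = np.linspace(b_lo, b_hi, 41)
        ll = np.array([[logistic_loglik_counts(a, b, case_counts, ctrl_counts)
                        for b in b_grid] for a in a_grid])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (a_grid[i], b_grid[j])
        da = (a_hi - a_lo) / 40
        db = (b_hi - b_lo) / 40
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    return best[1]


def hwe_exact_p(n_AA, n_Aa, n_aa):
    """Exact conditional Hardy-Weinberg test (two-sided, by probability
    ordering over heterozygote counts at fixed allele counts)."""
    import math

    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    probs = {}
    for het in range(nA % 2, min(nA, 2 * n - nA) + 1, 2):
        hom_a = (nA - het) // 2
        hom_b = n - hom_a - het
        if hom_b < 0:
            continue
        logp = (math.lgamma(n + 1) - math.lgamma(hom_a + 1) -
                math.lgamma(het + 1) - math.lgamma(hom_b + 1) +
                het * math.log(2.0))
        probs[het] = logp
    mx = max(probs.values())
    weights = {h: math.exp(lp - mx) for h, lp in probs.items()}
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs * (1 + 1e-12)) / total


def floated_contrast_errors(floated, cov):
    """Relative errors of every pairwise contrast variance under floated
    (quasi-)variances; cov is the non-reference coefficient covariance."""
    k1 = cov.shape[0]
    errs = []
    for j in range(k1):
        target = cov[j, j]
        errs.append((floated[0] + floated[j + 1]) / target - 1.0)
    for i, j in itertools.combinations(range(k1), 2):
        target = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        errs.append((floated[i + 1] + floated[j + 1]) / target - 1.0)
    return np.asarray(errs)


def ols_slope_by_normal_equations(score, trait, covariates=None):
    X = [np.ones(len(score)), np.asarray(score, dtype=float)]
    if covariates is not None:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        X.extend(arr.T)
    X = np.column_stack(X)
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(trait, dtype=float))
    return beta[1]
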
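"""Adiposity stratification and gene-adiposity interaction analysis.

BMI strata follow the WHO Asian cut-points: normal < 23 kg/m2, overweight
23 to < 27.5, obese >= 27.5. Waist circumference, waist-hip ratio and
percent body fat are stratified by sex-specific tertiles computed on the
analysis sample (boundary ties assigned to the lower tertile).

Interaction is tested in a single logistic model with the score, the
adiposity variable and their product, adjusted for age, sex and centre;
the Wald p of the product term is reported. Both a continuous-variable and
an ordinal stratum-coded variant are available because either
parameterisation is defensible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core import Z95

WHO_ASIAN_BMI_CUTS = (23.0, 27.5)
BMI_LABELS = ("normal", "overweight", "obese")
TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class StratumScheme:
    """How to cut one adiposity variable into strata."""

    variable: str
    mode: str = "sex_specific_tertiles"  # or "fixed_cutpoints"
    cutpoints: tuple = WHO_ASIAN_BMI_CUTS  # used in fixed mode
    labels: tuple = ()

    def __post_init__(self):
        if self.mode not in ("fixed_cutpoints", "sex_specific_tertiles"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cut-points must be strictly increasing")
        if not self.labels:
            self.labels = (BMI_LABELS if self.mode == "fixed_cutpoints"
                           else TERTILE_LABELS)


def define_strata(values, sex=None, scheme: StratumScheme | None = None) -> np.ndarray:
    """Stratum labels for each individual.

    Fixed mode bins on the scheme cut-points (value == cut goes to the
    upper class, matching 'normal < 23 <= overweight'). Tertile mode
    computes cut-points within each sex; boundary ties go to the lower
    tertile.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    scheme = scheme or StratumScheme(variable="bmi", mode="fixed_cutpoints")
    if scheme.mode == "fixed_cutpoints":
        idx = np.searchsorted(np.asarray(scheme.cutpoints), values, side="right")
        return np.asarray(scheme.labels, dtype=object)[idx]
    if sex is None:
        raise ValueError("sex labels required for sex-specific tertiles")
    sex = np.asarray(sex)
    out = np.empty(len(values), dtype=object)
    for s in np.unique(sex):
        rows = sex == s
        v = values[rows]
        if np.ptp(v) == 0:
            raise ValueError(f"constant variable within sex {s!r}")
        cuts = np.quantile(v, [1 / 3, 2 / 3])
        idx = np.searchsorted(cuts, v, side="left")
        out[rows] = np.asarray(scheme.labels, dtype=object)[idx]
    return out


def _logistic_fit(X: pd.DataFrame, y: np.ndarray):
    X = sm.add_constant(X.astype(float), has_constant="add")
    return sm.GLM(np.asarray(y), X, family=sm.families.Binomial()).fit()


def stratified_grs_association(score, y, covariates, labels,
                               stratum_order=None) -> pd.DataFrame:
    """Independent per-stratum logistic fits of disease on the score.

    Single-class strata are flagged and omitted from estimates rather than
    raising.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y)
    labels = np.asarray(labels)
    cov_df = None if covariates is None else pd.DataFrame(covariates).reset_index(drop=True)
    order = stratum_order if stratum_order is not None else pd.unique(labels)
    rows = []
    for lab in order:
        sel = labels == lab
        n_case = int((y[sel] == 1).sum())
        n_ctrl = int((y[sel] == 0).sum())
        if n_case == 0 or n_ctrl == 0:
            rows.append(dict(stratum=lab, n_cases=n_case, n_controls=n_ctrl,
                             or_=np.nan, ci_low=np.nan, ci_high=np.nan,
                             p=np.nan, flag="single_class"))
            continue
        X = pd.DataFrame({"score": score[sel]})
        if cov_df is not None:
            # drop constant covariate columns within the stratum (e.g. a
            # centre indicator with no members here)
            sub = cov_df.iloc[np.flatnonzero(sel)].reset_index(drop=True)
            sub = sub.loc[:, sub.nunique() > 1]
            X = pd.concat([X, sub], axis=1)
        fit = _logistic_fit(X, y[sel])
        b, se = float(fit.params["score"]), float(fit.bse["score"])
        rows.append(dict(stratum=lab, n_cases=n_case, n_controls=n_ctrl,
                         or_=float(np.exp(b)),
                         ci_low=float(np.exp(b - Z95 * se)),
                         ci_high=float(np.exp(b + Z95 * se)),
                         p=float(2.0 * stats.norm.sf(abs(b) / se)), flag=None))
    return pd.DataFrame(rows)


@dataclass
class InteractionResult:
    coef: float  # log-OR change in per-point score effect per variable unit
    se: float
    p_interaction: float
    score_main: float
    variable_main: float
    per_stratum: pd.DataFrame | None = field(default=None, repr=False)


def grs_interaction_test(score, variable, y, covariates=None,
                         center: bool = True) -> InteractionResult:
    """Single logistic model: score + variable + score x variable (+ adj).

    ``variable`` may be the continuous adiposity measure or an ordinal
    stratum coding. Main-effect terms are centred by default so the
    product column is not near-collinear with them.
    """
    score = np.asarray(score, dtype=float)
    variable = np.asarray(variable, dtype=float)
    y = np.asarray(y)
    s = score - score.mean() if center else score
    v = variable - variable.mean() if center else variable
    X = pd.DataFrame({"score": s, "variable": v, "score_x_variable": s * v})
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    M = sm.add_constant(X.astype(float), has_constant="add").to_numpy()
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("collinear design: interaction model is not identifiable")
    fit = _logistic_fit(X, y)
    b = float(fit.params["score_x_variable"])
    se = float(fit.bse["score_x_variable"])
    return InteractionResult(
        coef=b, se=se, p_interaction=float(2.0 * stats.norm.sf(abs(b) / se)),
        score_main=float(fit.params["score"]),
        variable_main=float(fit.params["variable"]))


def grs_trait_association(score, trait, covariates=None):
    """Least-squares slope of a continuous trait on the rescaled score,
    adjusted for covariates. Returns (slope, se, p)."""
    score = np.asarray(score, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if np.std(score) == 0 or np.std(trait) == 0:
        raise ValueError("zero variance in score or trait")
    X = pd.DataFrame({"score": score})
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.OLS(trait, X).fit()
    return (float(fit.params["score"]), float(fit.bse["score"]),
            float(fit.pvalues["score"]))


def interaction_table(profiles: dict, y, covariates, strata_labels: dict,
                      variables: dict) -> pd.DataFrame:
    """Tidy strata x scores association table with interaction p-values.

    ``profiles`` maps score name -> per-individual rescaled score;
    ``strata_labels`` maps adiposity variable -> stratum labels;
    ``variables`` maps adiposity variable -> continuous values.
    """
    rows = []
    for var, labels in strata_labels.items():
        for name, score in profiles.items():
            per = stratified_grs_association(score, y, covariates, labels)
            inter = grs_interaction_test(score, variables[var], y, covariates)
            for r in per.itertuples():
                rows.append(dict(variable=var, stratum=r.stratum, grs=name,
                                 n_cases=r.n_cases, n_controls=r.n_controls,
                                 or_=r.or_, ci_low=r.ci_low, ci_high=r.ci_high,
                                 p=r.p, p_interaction=inter.p_interaction))
    return pd.DataFrame(rows)
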
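"""Synthetic cohort, discovery-study and biased-sampling generators.

Everything downstream (QC, association, meta-analysis, shrinkage, risk
scores, discrimination, interaction) is exercised against cohorts generated
here with known ground truth, because the individual-level data the methods
were designed for are access-controlled.

Model
-----
Genotypes are drawn independently per SNP under Hardy-Weinberg proportions
at the stated risk-allele frequency (no linkage disequilibrium, no
population structure, no relatedness). Disease follows a logistic model

    logit P(case) = b0 + sum_j beta_j g_j + covariate terms
                    + gamma * (adiposity - ref) * (allele count - expected)

where b0 is solved by bisection so the expected prevalence over the
simulated covariate distribution hits the target (default 7.6%, the
prevalence of the motivating cohort). ``severity`` is the latent linear
predictor plus standard logistic noise: cases are exactly the individuals
with severity > 0, which gives biased ("clear-cut case") sampling designs an
explicit, testable definition.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import GenotypeMatrix, rng_from_seed, sigmoid

ADIPOSITY_VARS = ("bmi", "wc", "whr", "pbf")

# Baseline anthropometry of the emulated cohort by sex: mean and SD for
# BMI (kg/m2), waist circumference (cm), waist-hip ratio and percent body
# fat, plus age (years) and the male fraction.
_MALE_ADIPOSITY = {"bmi": (23.4, 3.2), "wc": (82.0, 9.7), "whr": (0.90, 0.06), "pbf": (21.9, 6.2)}
_FEMALE_ADIPOSITY = {"bmi": (23.8, 3.5), "wc": (79.1, 9.6), "whr": (0.87, 0.07), "pbf": (32.1, 7.2)}

# Plausible cross-correlations between adiposity measures (bmi, wc, whr, pbf).
_ADIPOSITY_CORR = np.array([
    [1.00, 0.80, 0.45, 0.65],
    [0.80, 1.00, 0.70, 0.60],
    [0.45, 0.70, 1.00, 0.45],
    [0.65, 0.60, 0.45, 1.00],
])


@dataclass
class SnpSpec:
    """One simulated variant: frequency, true per-allele log-OR, mechanism."""

    snp_id: str
    raf: float
    beta_true: float = 0.0
    mechanism: str = "other"  # 'BC', 'IR' or 'other'
    missing_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.raf <= 1.0:
            raise ValueError(f"{self.snp_id}: raf must be in [0,1], got {self.raf}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"{self.snp_id}: missing_rate must be in [0,1)")
        if not np.isfinite(self.beta_true):
            raise ValueError(f"{self.snp_id}: beta_true must be finite")


@dataclass
class CovariateModel:
    """Covariate distribution and its effects on the disease log-odds."""

    age_mean: float = 51.4
    age_sd: float = 10.7
    prop_male: float = 0.405
    male_adiposity: dict = field(default_factory=lambda: dict(_MALE_ADIPOSITY))
    female_adiposity: dict = field(default_factory=lambda: dict(_FEMALE_ADIPOSITY))
    adiposity_corr: np.ndarray = field(default_factory=lambda: _ADIPOSITY_CORR.copy())
    # log-OR per year of age, for female sex, per BMI unit; centre effects
    # are drawn N(0, centre_sd) per centre.
    beta_age: float = 0.04
    beta_female: float = 0.10
    beta_bmi: float = 0.10
    centre_sd: float = 0.20


@dataclass
class SimConfig:
    n_individuals: int
    snps: list
    n_centres: int = 10
    target_prevalence: float = 0.076
    covariates: CovariateModel = field(default_factory=CovariateModel)
    interaction_coef: float = 0.0  # log-OR change in per-allele effect per BMI unit
    seed: int = 0

    def __post_init__(self):
        if self.n_centres < 1:
            raise ValueError("n_centres must be >= 1")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0,1)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class DiscoveryDesign:
    """Case-control discovery study with optional extreme-phenotype sampling.

    ``case_severity_quantile`` q keeps only the top (1-q) most severe cases;
    ``control_hypernormal`` additionally restricts controls to their
    bottom (1-q) severity tail ("hypernormal" controls).
    """

    n_cases: int
    n_controls: int
    alpha_select: float = 5e-8
    case_severity_quantile: float = 0.0
    control_hypernormal: bool = False
    prevalence: float = 0.076

    def __post_init__(self):
        if not 0.0 < self.alpha_select < 1.0:
            raise ValueError("alpha_select must be in (0,1)")
        if not 0.0 <= self.case_severity_quantile <= 1.0:
            raise ValueError("case_severity_quantile must be in [0,1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class Cohort:
    """A simulated cohort: genotypes, phenotype/covariate table, truth."""

    genotypes: GenotypeMatrix
    table: pd.DataFrame  # iid, y, severity, age, is_female, centre, bmi, wc, whr, pbf
    truth: pd.DataFrame  # snp_id, raf, beta_true, mechanism
    intercept: float
    config: SimConfig

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy()


def simulate_genotypes(snps, n: int, seed=0) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes (binomial(2, raf)) with missingness."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng_from_seed(seed)
    m = len(snps)
    dosage = np.empty((n, m), dtype=float)
    for j, s in enumerate(snps):
        dosage[:, j] = rng.binomial(2, s.raf, size=n)
        if s.missing_rate > 0:
            miss = rng.random(n) < s.missing_rate
            dosage[miss, j] = np.nan
    ids = np.array([f"I{i:06d}" for i in range(n)])
    return GenotypeMatrix(individuals=ids, snps=[s.snp_id for s in snps], dosage=dosage)


def simulate_covariates(config: SimConfig, seed=0) -> pd.DataFrame:
    rng = rng_from_seed(seed)
    cm = config.covariates
    n = config.n_individuals
    age = rng.normal(cm.age_mean, cm.age_sd, size=n)
    is_female = (rng.random(n) >= cm.prop_male).astype(int)
    centre = rng.integers(0, config.n_centres, size=n)
    adip = np.empty((n, len(ADIPOSITY_VARS)))
    chol = np.linalg.cholesky(cm.adiposity_corr)
    z = rng.standard_normal((n, len(ADIPOSITY_VARS))) @ chol.T
    for k, v in enumerate(ADIPOSITY_VARS):
        mu_m, sd_m = cm.male_adiposity[v]
        mu_f, sd_f = cm.female_adiposity[v]
        mu = np.where(is_female == 1, mu_f, mu_m)
        sd = np.where(is_female == 1, sd_f, sd_m)
        adip[:, k] = mu + sd * z[:, k]
    df = pd.DataFrame({"age": age, "is_female": is_female, "centre": centre})
    for k, v in enumerate(ADIPOSITY_VARS):
        df[v] = adip[:, k]
    return df


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection on expected prevalence mean(sigmoid(b0 + eta)) = target."""

    def f(b0):
        return sigmoid(b0 + eta).mean() - target

    lo, hi = -40.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v) < tol:
            return mid
        if v > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _linear_predictor(G: GenotypeMatrix, config: SimConfig, cov: pd.DataFrame,
                      centre_effects: np.ndarray) -> np.ndarray:
    cm = config.covariates
    betas = np.array([s.beta_true for s in config.snps])
    rafs = np.array([s.raf for s in config.snps])
    # missing genotypes enter the generating model at their expectation
    dos = np.where(np.isnan(G.dosage), 2.0 * rafs, G.dosage)
    eta = dos @ betas
    eta += cm.beta_age * (cov["age"].to_numpy() - cm.age_mean)
    eta += cm.beta_female * cov["is_female"].to_numpy()
    eta += centre_effects[cov["centre"].to_numpy()]
    bmi_ref = 0.5 * (cm.male_adiposity["bmi"][0] + cm.female_adiposity["bmi"][0])
    bmi_c = cov["bmi"].to_numpy() - bmi_ref
    eta += cm.beta_bmi * bmi_c
    if config.interaction_coef != 0.0:
        allele_count = dos.sum(axis=1) - 2.0 * rafs.sum()
        eta += config.interaction_coef * bmi_c * allele_count
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return eta


def simulate_phenotype(G: GenotypeMatrix, config: SimConfig, covariates=None, seed=None):
    """Return (y, intercept, severity) for a genotype matrix.

    ``severity`` is the latent linear predictor plus standard logistic
    noise; y = (severity > 0) exactly, so prevalence is controlled through
    the intercept.
    """
    rng = rng_from_seed(config.seed if seed is None else seed)
    if covariates is None:
        covariates = simulate_covariates(config, rng)
    if len(covariates) != G.n_individuals:
        raise ValueError("genotypes and covariates are not row-aligned")
    centre_effects = rng.normal(0.0, config.covariates.centre_sd, size=config.n_centres)
    eta = _linear_predictor(G, config, covariates, centre_effects)
    b0 = _solve_intercept(eta, config.target_prevalence)
    severity = b0 + eta + rng.logistic(0.0, 1.0, size=len(eta))
    y = (severity > 0).astype(int)
    return y, b0, severity


def simulate_cohort(config: SimConfig) -> Cohort:
    """One-call generator: genotypes + covariates + phenotype + truth table."""
    rng = rng_from_seed(config.seed)
    G = simulate_genotypes(config.snps, config.n_individuals, rng)
    cov = simulate_covariates(config, rng)
    y, b0, severity = simulate_phenotype(G, config, covariates=cov, seed=rng)
    table = cov.copy()
    table.insert(0, "iid", G.individuals)
    table["y"] = y
    table["severity"] = severity
    truth = pd.DataFrame({
        "snp_id": [s.snp_id for s in config.snps],
        "raf": [s.raf for s in config.snps],
        "beta_true": [s.beta_true for s in config.snps],
        "mechanism": [s.mechanism for s in config.snps],
    })
    return Cohort(genotypes=G, table=table, truth=truth, intercept=b0, config=config)


# ---------------------------------------------------------------------------
# Discovery-study simulation (winner's curse / spectrum bias machinery)
# ---------------------------------------------------------------------------

def _genotype_probs(raf: float) -> np.ndarray:
    q = 1.0 - raf
    return np.array([q * q, 2 * raf * q, raf * raf])


def _severity_threshold(lp: np.ndarray, fg: np.ndarray, base: np.ndarray,
                        keep_frac: float, case: bool) -> float:
    """Severity cut keeping ``keep_frac`` of cases (top tail) or controls
    (bottom tail), using P(severity > t | g) = sigmoid(lp_g - t)."""
    total = (fg * base).sum()

    def kept(t):
        if case:
            return (fg * sigmoid(lp - t)).sum() / total
        return (fg * (1.0 - sigmoid(lp - t))).sum() / total

    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if kept(mid) > keep_frac:
            lo, hi = (mid, hi) if case else (lo, mid)
        else:
            lo, hi = (lo, mid) if case else (mid, hi)
    return 0.5 * (lo + hi)


def discovery_sampling_probs(spec: SnpSpec, design: DiscoveryDesign):
    """Genotype distributions among sampled cases and controls.

    Cases are individuals with latent severity > 0 under the single-SNP
    logistic model at the design prevalence; extreme-phenotype designs
    shift the severity cut-offs.
    """
    fg = _genotype_probs(spec.raf)
    g = np.array([0.0, 1.0, 2.0])
    eta = spec.beta_true * g
    b0 = _solve_intercept_weighted(eta, fg, design.prevalence)
    lp = b0 + eta
    p_case = sigmoid(lp)
    p_ctrl = 1.0 - p_case
    q = design.case_severity_quantile
    if q > 0.0:
        t = _severity_threshold(lp, fg, p_case, 1.0 - q, case=True)
        t = max(t, 0.0)  # severe cases are still cases
        p_case = sigmoid(lp - t)
        if design.control_hypernormal:
            u = _severity_threshold(lp, fg, 1.0 - sigmoid(lp), 1.0 - q, case=False)
            u = min(u, 0.0)
            p_ctrl = 1.0 - sigmoid(lp - u)
    case_probs = fg * p_case
    ctrl_probs = fg * p_ctrl
    return case_probs / case_probs.sum(), ctrl_probs / ctrl_probs.sum()


def _solve_intercept_weighted(eta, w, target, tol=1e-10):
    def f(b0):
        return (w * sigmoid(b0 + eta)).sum() / w.sum() - target

    return optimize.brentq(f, -60.0, 60.0, xtol=tol)


def simulate_discovery(snps, design: DiscoveryDesign, reps: int, seed=0) -> pd.DataFrame:
    """Replicate case-control discovery studies per SNP.

    Each replicate draws genotype counts for cases and controls from the
    (possibly extreme-sampled) genotype distributions, fits the per-allele
    logistic model on the collapsed counts and flags the replicate as
    selected when its Wald p-value passes ``alpha_select`` — the selection
    mechanism behind the winner's curse. All estimates are retained.
    """
    from .association import fit_counts_logistic  # deferred import cycle

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng_from_seed(seed)
    rows = []
    for spec in snps:
        pc, pn = discovery_sampling_probs(spec, design)
        case_counts = rng.multinomial(design.n_cases, pc, size=reps)
        ctrl_counts = rng.multinomial(design.n_controls, pn, size=reps)
        for r in range(reps):
            beta, se, p, flag = fit_counts_logistic(case_counts[r], ctrl_counts[r])
            rows.append((spec.snp_id, r, beta, se, p, bool(p < design.alpha_select),
                         spec.beta_true))
    return pd.DataFrame(rows, columns=["snp_id", "rep", "beta_hat", "se_hat", "p",
                                       "selected", "beta_true"])


def simulate_spectrum_bias(cohort: Cohort, design: DiscoveryDesign, seed=0) -> np.ndarray:
    """Row indices of a biased subsample of a simulated cohort.

    Keeps the top (1 - q) of cases by latent severity and, when
    ``control_hypernormal``, the bottom (1 - q) of controls, emulating
    studies of clear-cut cases and hypernormal controls.
    """
    sev = cohort.table["severity"].to_numpy()
    y = cohort.y
    q = design.case_severity_quantile
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if q > 0.0:
        cut = np.quantile(sev[case_idx], q)
        case_idx = case_idx[sev[case_idx] >= cut]
        if design.control_hypernormal:
            cut_c = np.quantile(sev[ctrl_idx], 1.0 - q)
            ctrl_idx = ctrl_idx[sev[ctrl_idx] <= cut_c]
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("biased subsample leaves fewer than 2 cases or controls")
    return np.sort(np.concatenate([case_idx, ctrl_idx]))


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write genotype TSV, cohort table TSV and truth file; return paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.tsv",
    }
    gdf = cohort.genotypes.to_frame()
    gdf.to_csv(paths["genotypes"], sep="\t", na_rep="NA")
    cohort.table.to_csv(paths["cohort"], sep="\t", index=False)
    truth = cohort.truth.copy()
    truth["seed"] = cohort.config.seed
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
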
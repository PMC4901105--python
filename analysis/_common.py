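"""Shared setup for the numbered analysis scripts: one canonical synthetic
cohort emulating the study conditions (52-SNP panel at published
frequencies with population-scale effects, ten centres, 7.6% prevalence),
and the results directory layout."""
from pathlib import Path

from t2dgrs import panel
from t2dgrs.simulate import Cohort, SimConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

DEFAULT_N = 20_000
DEFAULT_SEED = 2016


def study_cohort(seed: int = DEFAULT_SEED, n: int = DEFAULT_N,
                 missing_rate: float = 0.002) -> Cohort:
    # per-SNP missingness is kept low: with only 52 SNPs the per-sample
    # call-rate filter (>= 98%) already trips at two missing genotypes
    specs = panel.default_snp_specs("grs", missing_rate=missing_rate)
    return simulate_cohort(SimConfig(n_individuals=n, snps=specs, seed=seed))


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
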
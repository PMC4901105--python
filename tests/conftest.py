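import numpy as np
import pytest

from t2dgrs.simulate import SimConfig, SnpSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-person, 12-SNP cohort with known effects, shared read-only."""
    specs = [SnpSpec(f"s{i:02d}", raf=0.2 + 0.02 * i,
                     beta_true=float(np.log(1.05 + 0.02 * i)),
                     mechanism="BC" if i < 8 else "IR")
             for i in range(12)]
    return simulate_cohort(SimConfig(n_individuals=4000, snps=specs, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
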
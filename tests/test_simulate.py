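"""Synthetic cohort generator: genotype frequencies, prevalence control,
discovery selection and extreme-phenotype sampling."""
import numpy as np
import pytest
from scipy import stats

from t2dgrs.association import fit_counts_logistic, fit_snp_logistic
from t2dgrs.core import sigmoid
from t2dgrs.simulate import (DiscoveryDesign, SimConfig, SnpSpec,
                             simulate_cohort, simulate_discovery,
                             simulate_genotypes, simulate_spectrum_bias)


class TestSimulateGenotypes:
    @pytest.mark.parametrize("raf,expected", [(0.0, 0.0), (1.0, 2.0)])
    def test_degenerate_frequencies_give_constant_dosage(self, raf, expected):
        G = simulate_genotypes([SnpSpec("s", raf)], 500, seed=0)
        assert (G.dosage == expected).all()

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            SnpSpec("s", raf=1.2)
        with pytest.raises(ValueError):
            SnpSpec("s", raf=0.5, missing_rate=1.0)

    def test_mean_dosage_within_exact_binomial_interval(self):
        # 2n allele draws at raf 0.5: 99% interval for the allele count
        n = 10_000
        G = simulate_genotypes([SnpSpec("s", 0.5)], n, seed=42)
        lo, hi = stats.binom.interval(0.99, 2 * n, 0.5)
        assert lo <= G.dosage.sum() <= hi
        counts = [int((G.dosage == g).sum()) for g in (2, 1, 0)]
        from t2dgrs.qc import hwe_chi2_test

        _, p = hwe_chi2_test(*counts)
        assert p > 0.001

    def test_allele_frequency_convergence(self):
        n = 8_000
        rafs = [0.05, 0.3, 0.5, 0.9]
        G = simulate_genotypes([SnpSpec(f"s{i}", r) for i, r in enumerate(rafs)],
                               n, seed=7)
        obs = G.allele_frequency()
        bound = 3.0 * np.sqrt(np.array(rafs) * (1 - np.array(rafs)) / (2 * n))
        assert np.all(np.abs(obs - np.array(rafs)) < bound)

    def test_missingness_independent_of_genotype(self):
        G = simulate_genotypes([SnpSpec("s", 0.5, missing_rate=0.3)], 20_000, seed=3)
        miss = np.isnan(G.dosage[:, 0])
        assert 0.27 < miss.mean() < 0.33
        # observed frequency unchanged by missingness
        assert abs(np.nanmean(G.dosage) / 2 - 0.5) < 0.01


class TestSimulatePhenotype:
    def test_null_effects_hit_target_prevalence(self):
        n = 20_000
        specs = [SnpSpec(f"s{i}", 0.3, 0.0) for i in range(5)]
        cohort = simulate_cohort(SimConfig(n_individuals=n, snps=specs, seed=5))
        lo, hi = stats.binom.interval(0.99, n, 0.076)
        assert lo <= cohort.y.sum() <= hi

    def test_single_snp_effect_recovered_by_refit(self):
        specs = [SnpSpec("s", 0.3, float(np.log(1.2)))]
        cohort = simulate_cohort(SimConfig(n_individuals=50_000, snps=specs, seed=6))
        res = fit_snp_logistic(cohort.genotypes.dosage[:, 0], cohort.y)
        assert res.ci_low <= 1.20 <= res.ci_high

    def test_null_pvalues_uniform(self):
        # global null: per-SNP association p-values are uniform
        rng = np.random.default_rng(8)
        n, m = 5_000, 1_000
        fg = np.array([0.49, 0.42, 0.09])
        pvals = []
        for _ in range(m):
            n_case = rng.binomial(n, 0.1)
            c1 = rng.multinomial(n_case, fg)
            c0 = rng.multinomial(n - n_case, fg)
            _, _, p, flag = fit_counts_logistic(c1, c0)
            if flag is None:
                pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSimulateDiscovery:
    def test_null_selection_requires_threshold_z(self):
        specs = [SnpSpec("s", 0.3, 0.0)]
        design = DiscoveryDesign(2000, 2000, alpha_select=0.05)
        df = simulate_discovery(specs, design, reps=300, seed=9)
        z = np.abs(df.beta_hat / df.se_hat)
        assert np.all(z[df.selected] >= stats.norm.ppf(1 - 0.025) - 1e-9)
        assert np.all(z[~df.selected] < stats.norm.ppf(1 - 0.025) + 1e-9)

    def test_full_power_limit_is_unbiased(self):
        beta = float(np.log(1.5))
        specs = [SnpSpec("s", 0.3, beta)]
        design = DiscoveryDesign(20_000, 20_000, alpha_select=5e-8)
        df = simulate_discovery(specs, design, reps=200, seed=10)
        assert df.selected.mean() > 0.999
        sel = df[df.selected]
        assert abs(sel.beta_hat.mean() - beta) < 3 * sel.beta_hat.std() / np.sqrt(len(sel))

    def test_selected_z_matches_truncated_normal_oracle(self):
        # choose a design whose mean z is ~4, select at |z| >= z(5e-8)
        beta = float(np.log(1.13))
        specs = [SnpSpec("s", 0.3, beta)]
        design = DiscoveryDesign(5_000, 5_000, alpha_select=5e-8)
        df = simulate_discovery(specs, design, reps=4_000, seed=12)
        c = stats.norm.ppf(1 - design.alpha_select / 2)
        mu = (df.beta_hat / df.se_hat).mean()  # empirical non-centrality
        sel_z = (df.beta_hat / df.se_hat)[df.selected]
        # truncated-normal mean: mu + phi(c-mu)/(1-Phi(c-mu))
        expect = mu + stats.norm.pdf(c - mu) / stats.norm.sf(c - mu)
        mc_se = sel_z.std(ddof=1) / np.sqrt(len(sel_z))
        assert len(sel_z) > 100
        assert abs(sel_z.mean() - expect) < 3 * mc_se

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            DiscoveryDesign(0, 100)


@pytest.fixture(scope="module")
def plain_cohort():
    """Genotype-driven cohort without covariate effects: the latent
    severity is intercept + beta*g + logistic noise, so extreme-phenotype
    selection effects are cleanly attributable to the genotype."""
    from t2dgrs.simulate import CovariateModel

    cm = CovariateModel(beta_age=0.0, beta_female=0.0, beta_bmi=0.0,
                        centre_sd=0.0)
    specs = [SnpSpec("s", 0.3, float(np.log(2.0)))]
    return simulate_cohort(SimConfig(n_individuals=20_000, snps=specs,
                                     target_prevalence=0.25, covariates=cm,
                                     seed=13))


class TestSpectrumBias:
    def test_no_restriction_returns_full_cohort(self, plain_cohort):
        design = DiscoveryDesign(100, 100, case_severity_quantile=0.0)
        idx = simulate_spectrum_bias(plain_cohort, design, seed=0)
        assert len(idx) == plain_cohort.genotypes.n_individuals

    def test_expected_inflation_monotone_in_severity_restriction(self):
        # deterministic: expected log-OR from the sampling distributions
        from t2dgrs.simulate import discovery_sampling_probs

        spec = SnpSpec("s", 0.3, float(np.log(1.3)))
        N = 1e7

        def expected_beta(q, hyper):
            d = DiscoveryDesign(100, 100, case_severity_quantile=q,
                                control_hypernormal=hyper)
            pc, pn = discovery_sampling_probs(spec, d)
            beta, _, _, _ = fit_counts_logistic(pc * N, pn * N)
            return beta

        b0, b5, b8 = (expected_beta(q, False) for q in (0.0, 0.5, 0.8))
        assert b0 == pytest.approx(spec.beta_true, abs=1e-3)
        assert b0 < b5 < b8
        # hypernormal controls inflate at least as much as case restriction
        assert expected_beta(0.5, True) > b5

    def test_severe_case_restriction_inflates_cohort_refit(self, plain_cohort):
        c = plain_cohort
        g = c.genotypes.dosage[:, 0]
        full = fit_snp_logistic(g, c.y)
        d_case = DiscoveryDesign(100, 100, case_severity_quantile=0.7)
        d_both = DiscoveryDesign(100, 100, case_severity_quantile=0.7,
                                 control_hypernormal=True)
        i1 = simulate_spectrum_bias(c, d_case, seed=0)
        i2 = simulate_spectrum_bias(c, d_both, seed=0)
        b1 = fit_snp_logistic(g[i1], c.y[i1]).beta
        b2 = fit_snp_logistic(g[i2], c.y[i2]).beta
        assert abs(b1) > abs(full.beta)
        assert abs(b2) >= abs(b1)

    def test_too_restrictive_subset_raises(self, plain_cohort):
        design = DiscoveryDesign(100, 100, case_severity_quantile=0.9999)
        with pytest.raises(ValueError):
            simulate_spectrum_bias(plain_cohort, design, seed=0)


def test_interaction_null_pvalues_uniform():
    from t2dgrs.strata import grs_interaction_test

    rng = np.random.default_rng(14)
    pvals = []
    for _ in range(300):
        n = 600
        score = rng.binomial(2, 0.3, size=(n, 8)).sum(axis=1).astype(float)
        bmi = rng.normal(23.6, 3.4, size=n)
        eta = -2.0 + 0.05 * (score - score.mean()) + 0.06 * (bmi - bmi.mean())
        y = (rng.random(n) < sigmoid(eta)).astype(int)
        pvals.append(grs_interaction_test(score, bmi, y).p_interaction)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
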
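"""Genetic risk scores: imputation, rescaling, mechanism classes,
variance explained, quartile floating absolute risks."""
import numpy as np
import pandas as pd
import pytest

from _oracles import floated_contrast_errors
from t2dgrs.core import GenotypeMatrix, sigmoid
from t2dgrs.grs import (EvidenceRecord, GrsDefinition, WeightScheme,
                        classify_mechanism, compute_grs, floated_variances,
                        impute_missing_by_centre_mean, quantile_bins,
                        quartile_association, variance_explained)
from t2dgrs.association import fit_snp_logistic
from t2dgrs.simulate import SnpSpec, simulate_genotypes


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(np.arange(dosage.shape[0]).astype(str),
                          [f"s{j}" for j in range(dosage.shape[1])], dosage)


class TestCentreMeanImputation:
    def test_complete_matrix_unchanged(self):
        G = _matrix([[0, 1], [2, 1], [1, 0]])
        out = impute_missing_by_centre_mean(G, ["a", "a", "b"])
        np.testing.assert_array_equal(out.dosage, G.dosage)

    def test_centre_mean_fill(self):
        G = _matrix([[0], [2], [np.nan], [2]])
        out = impute_missing_by_centre_mean(G, ["a", "a", "a", "b"])
        assert out.dosage[2, 0] == pytest.approx(1.0)

    def test_empty_centre_falls_back_to_overall_mean(self):
        G = _matrix([[0], [2], [np.nan], [np.nan], [2]])
        with pytest.warns(UserWarning, match="overall mean"):
            out = impute_missing_by_centre_mean(G, ["a", "a", "b", "b", "a"])
        # overall mean of observed = 4/3
        np.testing.assert_allclose(out.dosage[2:4, 0], 4 / 3)

    def test_fully_missing_snp_rejected(self):
        G = _matrix([[np.nan], [np.nan]])
        with pytest.raises(ValueError):
            impute_missing_by_centre_mean(G, ["a", "a"])


class TestComputeGrs:
    def test_equal_weights_equal_allele_count(self):
        G = _matrix([[0, 1, 2], [2, 2, 2], [1, 0, 0]])
        d = GrsDefinition("u", ["s0", "s1", "s2"],
                          WeightScheme.unweighted_for(["s0", "s1", "s2"]))
        prof = compute_grs(G, d)
        np.testing.assert_allclose(prof.rescaled, G.dosage.sum(axis=1))
        np.testing.assert_allclose(prof.raw, prof.rescaled)

    def test_rescaling_arithmetic(self):
        G = _matrix([[2, 1]])
        d = GrsDefinition("w", ["s0", "s1"],
                          WeightScheme("w", {"s0": 0.1, "s1": 0.3}))
        prof = compute_grs(G, d)
        assert prof.raw[0] == pytest.approx(0.5)
        assert prof.rescaled[0] == pytest.approx(0.5 * 4 / (2 * 0.4))  # 2.5

    def test_rescaled_and_raw_give_identical_z(self, small_cohort):
        from t2dgrs.panel import load_panel  # noqa: F401  (no panel needed)

        G = small_cohort.genotypes
        weights = {s.snp_id: max(s.beta_true, 0.01) for s in small_cohort.config.snps}
        d = GrsDefinition("w", list(weights), WeightScheme("w", weights))
        prof = compute_grs(G, d)
        y = small_cohort.y
        za = fit_snp_logistic(prof.raw, y)
        zb = fit_snp_logistic(prof.rescaled, y)
        assert za.beta / za.se == pytest.approx(zb.beta / zb.se, rel=1e-6)
        assert za.p == pytest.approx(zb.p, rel=1e-6)

    def test_equal_weighting_preserves_ranking(self, rng):
        G = simulate_genotypes([SnpSpec(f"s{i}", 0.3) for i in range(5)], 50, seed=1)
        ids = [f"s{i}" for i in range(5)]
        u = compute_grs(G, GrsDefinition("u", ids, WeightScheme.unweighted_for(ids)))
        w = compute_grs(G, GrsDefinition("w", ids,
                                         WeightScheme("w", {s: 0.25 for s in ids})))
        assert np.array_equal(np.argsort(u.rescaled, kind="stable"),
                              np.argsort(w.rescaled, kind="stable"))

    def test_nonpositive_weight_sum_rejected(self):
        G = _matrix([[1, 1]])
        d = GrsDefinition("bad", ["s0", "s1"],
                          WeightScheme("bad", {"s0": -0.2, "s1": 0.1}))
        with pytest.raises(ValueError):
            compute_grs(G, d)


class TestClassifyMechanism:
    def test_beta_cell_criterion(self):
        assert classify_mechanism(EvidenceRecord("x", homa_b_decreased=True)) == "BC"

    def test_ir_criterion_not_obesity_mediated(self):
        assert classify_mechanism(
            EvidenceRecord("x", fasting_insulin_up=True)) == "IR"

    def test_obesity_mediated_excluded_from_ir(self):
        assert classify_mechanism(
            EvidenceRecord("x", fasting_insulin_up=True,
                           obesity_mediated=True)) == "unclassified"

    def test_no_flags_unclassified(self):
        assert classify_mechanism(EvidenceRecord("x")) == "unclassified"

    def test_bc_precedence_configurable(self):
        e = EvidenceRecord("x", homa_b_decreased=True, homa_ir_increased=True)
        assert classify_mechanism(e) == "BC"
        assert classify_mechanism(e, bc_precedence=False) == "IR"


class TestVarianceExplained:
    def test_zero_effect_zero_pve(self):
        assert variance_explained(0.0, 0.02, 0.3, 10_000) == 0.0

    def test_plugin_formula(self):
        beta, se, p, n = 0.1, 0.02, 0.3, 10_000
        num = 2 * beta**2 * p * (1 - p)
        expected = num / (num + se**2 * 2 * n * p * (1 - p))
        assert variance_explained(beta, se, p, n) == pytest.approx(expected,
                                                                   abs=1e-12)

    def test_monotone_in_effect_size(self):
        vals = [variance_explained(b, 0.02, 0.3, 5_000)
                for b in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(vals) > 0)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.02, 0.0, 1_000)


class TestQuartiles:
    def test_boundary_ties_assigned_to_lower_bin(self):
        v = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        bins = quantile_bins(v)
        # values equal to a cut-point stay in the lower quartile
        cut = np.quantile(v, 0.25)
        assert np.all(bins[v == cut] == 0)

    def test_null_score_gives_unit_ors(self, rng):
        score = rng.normal(size=6_000)
        y = (rng.random(6_000) < 0.1).astype(int)
        out = quartile_association(score, y)
        assert np.all(np.abs(np.log(out.or_)) < 0.35)

    def test_two_level_floating_variance_exact(self, rng):
        score = rng.normal(size=4_000)
        y = (rng.random(4_000) < sigmoid(-2.0 + 0.5 * score)).astype(int)
        out = quartile_association(score, y, n_bins=2)
        # the only contrast variance must be reproduced exactly
        contrast = out.float_var.sum()
        fit_var = None
        import statsmodels.api as sm

        bins = quantile_bins(score, 2)
        X = sm.add_constant(pd.DataFrame({"q": bins.astype(float)}))
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fit_var = float(fit.cov_params().loc["q", "q"])
        assert contrast == pytest.approx(fit_var, rel=1e-6)

    def test_four_level_contrast_variances_within_5pct(self, rng):
        score = rng.normal(size=8_000)
        y = (rng.random(8_000) < sigmoid(-2.2 + 0.4 * score)).astype(int)
        bins = quantile_bins(score, 4)
        X = pd.get_dummies(pd.Series(bins, name="q"), prefix="q",
                           drop_first=True, dtype=float)
        import statsmodels.api as sm

        fit = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        cov = fit.cov_params().iloc[1:, 1:].to_numpy()
        fv = floated_variances(cov)
        errs = floated_contrast_errors(fv, cov)
        assert np.max(np.abs(errs)) < 0.05

    def test_monotone_risk_gives_monotone_ors(self, rng):
        score = rng.normal(size=10_000)
        y = (rng.random(10_000) < sigmoid(-2.5 + 0.6 * score)).astype(int)
        out = quartile_association(score, y)
        assert np.all(np.diff(out.log_or) > 0)
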
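"""Adiposity strata, stratified associations, interaction tests and
GRS-trait association."""
import numpy as np
import pandas as pd
import pytest

from _oracles import ols_slope_by_normal_equations
from t2dgrs.core import sigmoid
from t2dgrs.strata import (StratumScheme, define_strata,
                           grs_interaction_test, grs_trait_association,
                           stratified_grs_association)


class TestDefineStrata:
    def test_who_asian_bmi_boundaries(self):
        labels = define_strata(np.array([22.9, 23.0, 27.4, 27.5]),
                               scheme=StratumScheme("bmi", "fixed_cutpoints"))
        assert list(labels) == ["normal", "overweight", "overweight", "obese"]

    def test_uniform_tertiles_balanced_within_sex(self, rng):
        v = rng.uniform(60, 100, size=600)
        sex = np.repeat([0, 1], 300)
        labels = define_strata(v, sex, StratumScheme("wc"))
        for s in (0, 1):
            counts = pd.Series(labels[sex == s]).value_counts()
            assert counts.max() - counts.min() <= 1

    def test_tertile_boundaries_match_sorting_oracle(self):
        v = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0, 8.0, 4.0, 6.0])
        sex = np.zeros(9, dtype=int)
        labels = define_strata(v, sex, StratumScheme("wc"))
        order = np.argsort(v)
        expected = np.empty(9, dtype=object)
        expected[order[:3]] = "low"
        expected[order[3:6]] = "medium"
        expected[order[6:]] = "high"
        assert list(labels) == list(expected)

    def test_constant_variable_rejected_in_tertile_mode(self):
        with pytest.raises(ValueError):
            define_strata(np.ones(10), np.zeros(10), StratumScheme("wc"))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            define_strata(np.array([1.0, np.nan]),
                          scheme=StratumScheme("bmi", "fixed_cutpoints"))


def _simulate_stratified(rng, n=30_000, interaction=0.0):
    score = rng.binomial(2, 0.3, size=(n, 10)).sum(axis=1).astype(float)
    bmi = rng.normal(23.6, 3.4, size=n)
    sc = score - score.mean()
    bc = bmi - bmi.mean()
    eta = -2.6 + 0.10 * sc + 0.08 * bc + interaction * sc * bc
    y = (rng.random(n) < sigmoid(eta)).astype(int)
    return score, bmi, y


class TestStratifiedAssociation:
    def test_homogeneous_effect_across_strata(self, rng):
        score, bmi, y = _simulate_stratified(rng, interaction=0.0)
        labels = define_strata(bmi, scheme=StratumScheme("bmi", "fixed_cutpoints"))
        out = stratified_grs_association(score, y, None, labels,
                                         stratum_order=["normal", "overweight",
                                                        "obese"])
        lo = np.log(out.or_)
        assert np.ptp(lo) < 0.08

    def test_negative_interaction_gives_declining_ors(self, rng):
        score, bmi, y = _simulate_stratified(rng, n=60_000, interaction=-0.02)
        labels = define_strata(bmi, scheme=StratumScheme("bmi", "fixed_cutpoints"))
        out = stratified_grs_association(score, y, None, labels,
                                         stratum_order=["normal", "overweight",
                                                        "obese"]).set_index("stratum")
        assert out.at["normal", "or_"] > out.at["obese", "or_"]

    def test_single_class_stratum_flagged(self, rng):
        score = rng.normal(size=100)
        y = np.concatenate([np.zeros(50, dtype=int),
                            (rng.random(50) < 0.3).astype(int)])
        labels = np.repeat(["a", "b"], 50)
        out = stratified_grs_association(score, y, None, labels).set_index("stratum")
        assert out.at["a", "flag"] == "single_class"
        assert np.isnan(out.at["a", "or_"])


class TestInteractionTest:
    def test_product_column_is_elementwise_product(self, rng):
        # deterministic coding check on the centred design
        score = rng.normal(size=50)
        v = rng.normal(size=50)
        s, vc = score - score.mean(), v - v.mean()
        X = pd.DataFrame({"score": s, "variable": vc,
                          "score_x_variable": s * vc})
        np.testing.assert_allclose(X.score_x_variable, X.score * X.variable)

    def test_interaction_coefficient_recovered(self, rng):
        coef = -0.02
        score, bmi, y = _simulate_stratified(rng, n=50_000, interaction=coef)
        res = grs_interaction_test(score, bmi, y)
        assert abs(res.coef - coef) < 3 * res.se

    def test_two_stratum_saturated_agreement(self, rng):
        # with a binary stratum indicator the interaction coefficient equals
        # the difference of the stratum log-ORs
        score, bmi, y = _simulate_stratified(rng, n=20_000, interaction=-0.03)
        ind = (bmi >= np.median(bmi)).astype(float)
        res = grs_interaction_test(score, ind, y, center=False)
        labels = np.where(ind == 1, "high", "low")
        out = stratified_grs_association(score, y, None, labels).set_index("stratum")
        diff = np.log(out.at["high", "or_"]) - np.log(out.at["low", "or_"])
        assert res.coef == pytest.approx(diff, abs=1e-6)

    def test_collinear_design_rejected(self, rng):
        score = rng.normal(size=100)
        with pytest.raises(ValueError):
            grs_interaction_test(score, score, (rng.random(100) < 0.5).astype(int))

    def test_collider_stratification_induces_apparent_heterogeneity(self):
        # score raises both adiposity and disease with no true interaction;
        # stratifying on adiposity (a collider of the score and the noise)
        # attenuates the middle stratum's fitted effect relative to the
        # open-ended tail strata, i.e. apparent heterogeneity
        n = 80_000
        diffs = []
        for seed in (5, 6, 7):
            rng = np.random.default_rng(seed)
            score = rng.binomial(2, 0.3, size=(n, 10)).sum(axis=1).astype(float)
            sc = score - score.mean()
            bmi = 23.6 + 1.5 * sc + rng.normal(0, 2.0, size=n)
            eta = -2.6 + 0.1 * sc + 0.25 * (bmi - bmi.mean())
            y = (rng.random(n) < sigmoid(eta)).astype(int)
            labels = define_strata(bmi, scheme=StratumScheme("bmi",
                                                             "fixed_cutpoints"))
            out = stratified_grs_association(
                score, y, None, labels,
                stratum_order=["normal", "overweight", "obese"])
            lo = np.log(out.or_.to_numpy())
            diffs.append(min(lo[0], lo[2]) - lo[1])
        assert np.mean(diffs) > 0.03  # middle stratum visibly attenuated


class TestTraitAssociation:
    def test_independent_trait_null_slope(self, rng):
        score = rng.normal(size=5_000)
        trait = rng.normal(size=5_000)
        slope, se, p = grs_trait_association(score, trait)
        assert abs(slope) < 3 * se

    def test_constructed_slope_recovered(self, rng):
        score = rng.normal(size=20_000)
        trait = -0.05 * score + rng.normal(0, 1.0, size=20_000)
        slope, se, _ = grs_trait_association(score, trait)
        assert abs(slope - (-0.05)) < 3 * se

    def test_matches_normal_equations_oracle(self, rng):
        score = rng.normal(size=10)
        cov = rng.normal(size=10)
        trait = 0.3 * score + 0.2 * cov + rng.normal(size=10)
        slope, _, _ = grs_trait_association(score, trait,
                                            pd.DataFrame({"c": cov}))
        assert slope == pytest.approx(
            ols_slope_by_normal_equations(score, trait, cov), abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            grs_trait_association(np.ones(10), rng.normal(size=10))
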
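import math

import numpy as np
import pytest

import triadgen as tg
from triadgen.io_plink import MISSING
from triadgen.traits import pathway_indicator_matrix


class TestPathwayIndicator:
    def test_all_loci_carry_variant(self):
        assert tg.pathway_indicator([1, 2, 1, 1], [0, 1, 2, 3]) == 1

    def test_one_locus_without_variant(self):
        assert tg.pathway_indicator([0, 2, 2, 2], [0, 1, 2, 3]) == 0

    def test_single_snp_pathway_dominant_coding(self):
        assert tg.pathway_indicator([0], [0]) == 0
        assert tg.pathway_indicator([2], [0]) == 1
        assert tg.pathway_indicator([1], [0]) == 1

    def test_missing_pathway_genotype_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            tg.pathway_indicator([MISSING, 1], [0, 1])

    def test_matrix_form_agrees_with_scalar(self, rng):
        g = rng.integers(0, 3, size=(20, 6))
        spec = tg.PathwaySpec([[0, 2], [3]])
        X = pathway_indicator_matrix(g, spec)
        for i in range(20):
            assert X[i, 0] == tg.pathway_indicator(g[i], [0, 2])
            assert X[i, 1] == tg.pathway_indicator(g[i], [3])

    def test_overlapping_pathways_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            tg.PathwaySpec([[0, 1], [1, 2]])


class TestLinearPredictorAndPenetrance:
    def test_baseline_only(self):
        m = tg.TraitModel("dichotomous", alpha=math.log(0.001), beta=[0.0, 0.0])
        assert tg.linear_predictor(m, np.zeros(2), 0) == pytest.approx(math.log(0.001))
        assert tg.penetrance(m, np.zeros(2), 0) == pytest.approx(0.001)

    def test_single_pathway_risk_product(self):
        m = tg.TraitModel(
            "dichotomous", alpha=math.log(0.00166), beta=np.log([1.65, 2.71])
        )
        eta = tg.linear_predictor(m, np.array([1.0, 0.0]), 0)
        assert eta == pytest.approx(math.log(0.00166 * 1.65))

    def test_two_pathways_combine_multiplicatively(self):
        m = tg.TraitModel(
            "dichotomous", alpha=math.log(0.00166), beta=np.log([1.65, 2.71])
        )
        assert tg.penetrance(m, np.array([1.0, 1.0]), 0) == pytest.approx(
            0.00166 * 1.65 * 2.71
        )

    def test_pure_interaction_scenario(self):
        m = tg.TraitModel(
            "dichotomous", alpha=math.log(0.00166), beta=[0.0, 0.0],
            theta=0.0, gamma=np.log([1.65, 2.71]), exposure_prevalence=0.5,
        )
        eta = tg.linear_predictor(m, np.array([1.0, 0.0]), 1)
        assert eta == pytest.approx(math.log(0.00166) + math.log(1.65))
        # without exposure the interaction vanishes (reduces to main-effects model)
        assert tg.linear_predictor(m, np.array([1.0, 0.0]), 0) == pytest.approx(
            math.log(0.00166)
        )

    def test_penetrance_above_one_rejected_at_construction(self):
        with pytest.raises(ValueError, match="penetrance"):
            tg.TraitModel("dichotomous", alpha=0.0, beta=[math.log(1.5)])

    def test_gxe_model_with_null_exposure_terms_equals_main_effects(self, rng):
        base = tg.TraitModel("dichotomous", alpha=math.log(0.01), beta=np.log([1.5, 2.0]))
        gxe = tg.TraitModel(
            "dichotomous", alpha=math.log(0.01), beta=np.log([1.5, 2.0]),
            theta=0.0, gamma=[0.0, 0.0], exposure_prevalence=0.3,
        )
        for _ in range(20):
            X = rng.integers(0, 2, size=2).astype(float)
            e = int(rng.integers(0, 2))
            assert tg.linear_predictor(gxe, X, e) == pytest.approx(
                tg.linear_predictor(base, X, 0)
            )

    def test_penetrance_monotone_in_indicators_for_positive_effects(self):
        m = tg.TraitModel("dichotomous", alpha=math.log(0.001), beta=np.log([1.3, 2.0]))
        vals = [tg.penetrance(m, np.array(x, dtype=float), 0)
                for x in ([0, 0], [1, 0], [1, 1])]
        assert vals[0] < vals[1] < vals[2]


class TestOrToRr:
    def test_identity_at_or_one(self):
        assert tg.or_to_rr(1.0, 0.3) == pytest.approx(1.0)

    def test_rare_disease_limit(self):
        assert tg.or_to_rr(2.5, 1e-6) == pytest.approx(2.5, rel=1e-4)

    def test_two_by_two_table_oracle(self):
        """RR from OR=2 at p0=0.5 reconstructs a 2x2 table with odds ratio 2."""
        rr = tg.or_to_rr(2.0, 0.5)
        assert rr == pytest.approx(4.0 / 3.0)
        p1 = rr * 0.5
        odds_ratio = (p1 / (1 - p1)) / (0.5 / (1 - 0.5))
        assert odds_ratio == pytest.approx(2.0)

    @pytest.mark.parametrize("p0", [0.01, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("rr", [0.5, 1.0, 1.8])
    def test_round_trip_inverse_of_rr_to_or(self, p0, rr):
        if rr * p0 >= 1:
            pytest.skip("risk above 1")
        p1 = rr * p0
        or_value = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert tg.or_to_rr(or_value, p0) == pytest.approx(rr)

    def test_or_scale_model_converts_cellwise(self):
        p0 = 0.2
        m = tg.TraitModel(
            "dichotomous", alpha=math.log(p0), beta=[math.log(2.0)],
            effect_scale="OR",
        )
        rr = tg.or_to_rr(2.0, p0)
        assert tg.penetrance(m, np.array([1.0]), 0) == pytest.approx(p0 * rr)


class TestAssignment:
    def test_exposure_prevalence_extremes(self, rng):
        m0 = tg.TraitModel("quantitative", alpha=0.0, beta=[0.0], exposure_prevalence=0.0)
        m1 = tg.TraitModel("quantitative", alpha=0.0, beta=[0.0], exposure_prevalence=1.0)
        assert tg.assign_exposure(m0, 100, rng).sum() == 0
        assert tg.assign_exposure(m1, 100, rng).sum() == 100

    def test_exposure_prevalence_mean(self, rng):
        m = tg.TraitModel("quantitative", alpha=0.0, beta=[0.0], exposure_prevalence=0.5)
        draws = tg.assign_exposure(m, 100_000, rng)
        assert abs(draws.mean() - 0.5) < 4 * 0.5 / np.sqrt(100_000)

    def test_dichotomous_assignment_frequency(self, rng):
        m = tg.TraitModel("dichotomous", alpha=math.log(0.00166), beta=[0.0])
        X = np.zeros((1_000_000, 1))
        y = tg.assign_dichotomous(m, X, np.zeros(len(X)), rng)
        se = np.sqrt(0.00166 * (1 - 0.00166) / len(X))
        assert abs(y.mean() - 0.00166) < 3 * se

    def test_quantitative_moments(self, rng):
        m = tg.TraitModel("quantitative", alpha=0.0, beta=[0.1, 0.15], sigma=1.0)
        X = np.tile([0.0, 1.0], (100_000, 1))
        y = tg.assign_quantitative(m, X, np.zeros(len(X)), rng)
        assert abs(y.mean() - 0.15) < 4 / np.sqrt(len(X))
        assert abs(y.var() - 1.0) < 0.02

    def test_quantitative_zero_noise_limit(self, rng):
        m = tg.TraitModel("quantitative", alpha=2.0, beta=[0.5], sigma=1e-12)
        y = tg.assign_quantitative(m, np.zeros((5, 1)), np.zeros(5), rng)
        assert np.allclose(y, 2.0)
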
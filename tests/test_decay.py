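"""The dispersal kernel: transforms, prediction, likelihood, fitting, GOF."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmgf.decay import (DecayCoefficients, fit, inv_logit, logit,
                        negative_log_likelihood, pearson_gof,
                        predict_frequency)
from pmgf.records import ScreeningRecord
from pmgf.simulate import GeneratorTruth, generate_screening
from pmgf.specs import ModelSpec


class TestTransforms:
    def test_symmetry_point(self):
        assert logit(0.5) == pytest.approx(0.0)
        assert inv_logit(0.0) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.01, 0.99))
    def test_round_trip(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)

    def test_extreme_negative_does_not_underflow_to_zero(self):
        val = inv_logit(-50.0)
        assert 0 < val < 1e-20
        assert val == pytest.approx(math.exp(-50), rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_logit_domain(self, bad):
        with pytest.raises(ValueError):
            logit(bad)


class TestPredict:
    def test_worked_value_at_source_edge(self, simple_coefficients):
        # -3.50 + e^0.26 + e^1.59 = 2.7007 on the log-odds scale
        eta = -3.50 + math.exp(0.26) + math.exp(1.59)
        p = predict_frequency(simple_coefficients, 0.0, "E", 2014)
        assert p == pytest.approx(inv_logit(eta), abs=1e-14)
        assert p == pytest.approx(0.9371, abs=5e-5)

    def test_far_field_asymptote_is_background_logodds(self, simple_coefficients):
        assert predict_frequency(simple_coefficients, 1e6, "E", 2014) == \
            pytest.approx(inv_logit(-3.50), abs=1e-12)

    def test_constant_model_with_zero_coefficients(self):
        coef = DecayCoefficients(
            spec=ModelSpec(2, "1", "1"),
            names=("beta0", "beta1", "gamma1", "beta2", "gamma2"),
            values=np.zeros(5), year_levels=(2014,))
        # two exp(0) = 1 terms on top of beta0 = 0
        for d in (0.0, 3.0, 50.0):
            assert predict_frequency(coef, d, "N", 2014) == \
                pytest.approx(inv_logit(2.0))

    def test_strictly_decreasing_under_negative_decay(self, simple_coefficients):
        grid = np.linspace(0, 60, 400)
        p = predict_frequency(simple_coefficients, grid, "E", 2014)
        assert np.all(np.diff(p) < 0)

    def test_unknown_levels_rejected(self, simple_coefficients):
        with pytest.raises(KeyError):
            predict_frequency(simple_coefficients, 1.0, "E", 1999)
        with pytest.raises(KeyError):
            predict_frequency(simple_coefficients, 1.0, "Q", 2014)


class TestLikelihood:
    def test_matches_brute_force_sum(self, simple_coefficients, small_records):
        nll = negative_log_likelihood(simple_coefficients, small_records)
        brute = 0.0
        for r in small_records:
            p = predict_frequency(simple_coefficients, r.distance_m,
                                  r.direction, r.year)
            brute -= (math.log(math.comb(r.n_screened, r.n_resistant))
                      + r.n_resistant * math.log(p)
                      + (r.n_screened - r.n_resistant) * math.log1p(-p))
        assert nll == pytest.approx(brute, abs=1e-10 * max(1, abs(brute)))

    def test_saturation_limit_all_successes(self):
        coef = DecayCoefficients(spec=ModelSpec(0), names=("beta0",),
                                 values=np.array([30.0]), year_levels=(2014,))
        recs = [ScreeningRecord(2014, "E", 1.0, 5, 5)]
        assert negative_log_likelihood(coef, recs) == pytest.approx(0.0,
                                                                    abs=1e-10)

    def test_truth_beats_perturbation_on_large_samples(
            self, simple_coefficients, small_records):
        nll_truth = negative_log_likelihood(simple_coefficients, small_records)
        worse = DecayCoefficients(
            spec=simple_coefficients.spec, names=simple_coefficients.names,
            values=simple_coefficients.values + np.array([0.3, -0.2, 0.5,
                                                          -0.3, 0.02]),
            year_levels=simple_coefficients.year_levels)
        assert nll_truth < negative_log_likelihood(worse, small_records)


class TestFit:
    def test_intercept_only_mle_is_pooled_proportion(self):
        recs = [ScreeningRecord(2014, "E", 1.0, 120, 30),
                ScreeningRecord(2014, "W", 4.0, 80, 50)]
        fs = fit(recs, ModelSpec(0), seed=0, n_starts=2)
        pooled = (30 + 50) / (120 + 80)
        assert inv_logit(fs.coefficients["beta0"]) == pytest.approx(pooled,
                                                                    abs=1e-10)
        assert fs.aic == -2 * fs.loglik + 2 * fs.k

    def test_recovers_scalar_kernel(self, small_records, simple_coefficients):
        fs = fit(small_records, simple_coefficients.spec, seed=1, n_starts=4)
        assert fs.converged
        se = fs.coefficients.se
        assert se is not None
        dev = np.abs(fs.coefficients.values - simple_coefficients.values)
        assert np.all(dev <= 4 * se)

    def test_double_spec_on_single_exponential_truth_nests(self, small_design):
        single = DecayCoefficients(
            spec=ModelSpec(1, "1", "1"), names=("beta0", "beta1", "gamma1"),
            values=np.array([-3.0, 1.2, -0.15]), year_levels=(2014,))
        recs = generate_screening(GeneratorTruth(
            coefficients=single, design=small_design, n_per_cell=3000, seed=21))
        ll_single = fit(recs, ModelSpec(1, "1", "1"), seed=2, n_starts=4).loglik
        ll_double = fit(recs, ModelSpec(2, "1", "1"), seed=2, n_starts=4).loglik
        assert ll_double >= ll_single - 1e-6
        assert ll_double - ll_single < 2.0

    def test_record_order_invariance(self, small_records):
        spec = ModelSpec(2, "1", "1")
        a = fit(small_records, spec, seed=3, n_starts=2)
        rng = np.random.default_rng(0)
        shuffled = list(small_records)
        rng.shuffle(shuffled)
        b = fit(shuffled, spec, seed=3, n_starts=2)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
        np.testing.assert_allclose(a.coefficients.values,
                                   b.coefficients.values, atol=1e-4)

    def test_reference_relabelling_leaves_predictions_unchanged(self):
        truth = GeneratorTruth(n_per_cell=800, seed=31)
        recs = [r for r in generate_screening(truth) if r.year == 2014]
        spec = ModelSpec(2, "direction", "1")
        fit_e = fit(recs, spec, seed=4, n_starts=2, ref_direction="E")
        fit_n = fit(recs, spec, seed=4, n_starts=2, ref_direction="N")
        for direction in ("E", "N", "SW"):
            for d in (0.5, 4.0, 25.0):
                pe = predict_frequency(fit_e.coefficients, d, direction, 2014)
                pn = predict_frequency(fit_n.coefficients, d, direction, 2014)
                assert pe == pytest.approx(pn, abs=1e-4)

    def test_constraints_and_term_ordering(self, small_records):
        fs = fit(small_records, ModelSpec(2, "1", "1"), seed=5, n_starts=4)
        c = fs.coefficients
        assert c["gamma1"] <= 0 and c["gamma2"] <= 0
        assert abs(c["gamma1"]) >= abs(c["gamma2"])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit([], ModelSpec(1), seed=0)
        same_dist = [ScreeningRecord(2014, "E", 1.0, 10, 5),
                     ScreeningRecord(2014, "W", 1.0, 10, 2)]
        with pytest.raises(ValueError, match="distances"):
            fit(same_dist, ModelSpec(1), seed=0)


class TestPearsonGof:
    def test_three_cell_hand_computation(self):
        coef = DecayCoefficients(spec=ModelSpec(0), names=("beta0",),
                                 values=np.array([logit(0.4)]),
                                 year_levels=(2014,))
        recs = [ScreeningRecord(2014, "E", 1.0, 10, 3),
                ScreeningRecord(2014, "E", 2.0, 20, 8),
                ScreeningRecord(2014, "E", 4.0, 30, 12)]
        from pmgf.decay import FitSummary
        fs = FitSummary(coefficients=coef, loglik=0.0, k=1,
                        converged=True, n_obs=3)
        gof = pearson_gof(fs, recs)
        # mu = (4, 8, 12): only the first cell deviates:
        # 10*(3-4)^2 / (4*6) = 0.41666...
        assert gof.chisq == pytest.approx(0.4166666666666667, abs=1e-10)
        assert gof.df == 1
        assert gof.dispersion == pytest.approx(gof.chisq / 1)

    def test_saturated_fit_has_zero_statistic(self):
        recs = [ScreeningRecord(2014, "E", 1.0, 50, 20)]
        fs = fit(recs, ModelSpec(0), seed=0, n_starts=1)
        gof = pearson_gof(fs, recs)
        assert gof.chisq == pytest.approx(0.0, abs=1e-8)
        assert not gof.valid  # df = 1 - 1 - 1 < 1
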
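"""Reduction distances (O50/O90) and binomial detection power."""

import math

import numpy as np
import pytest

from pmgf.decay import DecayCoefficients, FitSummary, inv_logit, predict_frequency
from pmgf.metrics import (PowerSpec, ReductionCI, UnattainableReductionError,
                          detection_power, min_sample_size, reduction_ci,
                          reduction_distance, reduction_table,
                          sample_size_table)
from pmgf.specs import ModelSpec


def _single_term(beta0, b, g):
    return DecayCoefficients(
        spec=ModelSpec(1, "1", "1"), names=("beta0", "beta1", "gamma1"),
        values=np.array([beta0, b, g]), year_levels=(2014,))


class TestReductionDistance:
    def test_o90_beyond_o50_and_limit_to_reference(self, simple_coefficients):
        o50 = reduction_distance(simple_coefficients, "E", 2014, 0.5, 0.5)
        o90 = reduction_distance(simple_coefficients, "E", 2014, 0.9, 0.5)
        assert 0.5 < o50 < o90
        near = reduction_distance(simple_coefficients, "E", 2014, 1e-7, 0.5)
        assert near == pytest.approx(0.5, abs=1e-2)

    def test_matches_fine_grid_search(self):
        """Brent root equals brute-force evaluation on a 1e-4 m grid."""
        rng = np.random.default_rng(12)
        for _ in range(8):
            coef = _single_term(rng.uniform(-5, -2.5), rng.uniform(0.5, 2.5),
                                rng.uniform(-0.3, -0.02))
            for red in (0.5, 0.9):
                try:
                    d_star = reduction_distance(coef, "E", 2014, red, 0.1)
                except UnattainableReductionError:
                    continue
                grid = np.arange(0.1, d_star + 1.0, 1e-4)
                p = predict_frequency(coef, grid, "E", 2014)
                target = (1 - red) * predict_frequency(coef, 0.1, "E", 2014)
                d_grid = grid[np.argmax(p < target)]
                assert abs(d_star - d_grid) <= 1e-3

    def test_target_below_asymptote_is_unattainable(self):
        # background 0.029; 90% reduction of a near frequency ~0.03 is below it
        coef = _single_term(-3.5, -1.0, -0.5)
        with pytest.raises(UnattainableReductionError):
            reduction_distance(coef, "E", 2014, 0.9, 0.1)

    def test_growing_arm_is_unattainable(self):
        coef = _single_term(-3.5, 1.0, 0.05)  # positive decay rate: growth
        with pytest.raises(UnattainableReductionError):
            reduction_distance(coef, "E", 2014, 0.5, 0.1)

    def test_reduction_domain(self, simple_coefficients):
        with pytest.raises(ValueError):
            reduction_distance(simple_coefficients, "E", 2014, 1.5, 0.5)


class TestReductionCI:
    def _fit_summary(self, coef, vcov):
        c = DecayCoefficients(spec=coef.spec, names=coef.names,
                              values=coef.values, vcov=vcov,
                              year_levels=coef.year_levels)
        return FitSummary(coefficients=c, loglik=0.0, k=c.k,
                          converged=True, n_obs=10)

    def test_zero_covariance_collapses_to_point(self, simple_coefficients):
        fs = self._fit_summary(simple_coefficients,
                               np.zeros((5, 5)))
        point = reduction_distance(simple_coefficients, "E", 2014, 0.5, 0.5)
        ci = reduction_ci(fs, "E", 2014, 0.5, 0.5, n_boot=200, seed=0)
        assert ci.lower == pytest.approx(point, abs=1e-9)
        assert ci.upper == pytest.approx(point, abs=1e-9)
        assert ci.reliable

    def test_inflated_covariance_widens_interval(self, simple_coefficients):
        v = np.diag([0.01, 0.01, 0.05, 0.005, 1e-5])
        widths = []
        for scale in (1.0, 4.0):
            fs = self._fit_summary(simple_coefficients, scale * v)
            ci = reduction_ci(fs, "E", 2014, 0.5, 0.5, n_boot=300, seed=3)
            widths.append(ci.upper - ci.lower)
        assert widths[1] > widths[0]

    def test_point_estimate_inside_interval(self, simple_coefficients):
        v = np.diag([0.01, 0.01, 0.05, 0.005, 1e-5])
        fs = self._fit_summary(simple_coefficients, v)
        ci = reduction_ci(fs, "E", 2014, 0.9, 0.5, n_boot=300, seed=1)
        point = reduction_distance(simple_coefficients, "E", 2014, 0.9, 0.5)
        assert ci.lower < point < ci.upper

    def test_minimum_bootstrap_size_enforced(self, simple_coefficients):
        fs = self._fit_summary(simple_coefficients, np.zeros((5, 5)))
        with pytest.raises(ValueError, match="n_boot"):
            reduction_ci(fs, "E", 2014, 0.5, 0.5, n_boot=50)

    def test_table_flags_unattainable_entries(self):
        # near-source p ~ 0.14, so a 90% reduction target (~0.014) lies
        # below the background asymptote (~0.029) and cannot be reached
        coef = _single_term(-3.5, 0.5, -0.05)
        fs = self._fit_summary(coef, None)
        # replace vcov=None summary (with_ci skipped automatically)
        tab = reduction_table(fs, {2014: 0.1}, with_ci=False)
        row = tab.iloc[0]
        assert math.isnan(row["o90_m"]) and "o90 unattainable" in row["note"]
        assert row["o50_m"] > 0


class TestDetectionPower:
    def test_basic_values(self):
        assert detection_power(1, 0.5) == pytest.approx(0.5)
        assert detection_power(1609, 0.001) == pytest.approx(0.8000734,
                                                             abs=1e-6)
        assert detection_power(1608, 0.001) < 0.8

    def test_monotone_in_n_and_p(self):
        assert detection_power(100, 0.01) < detection_power(200, 0.01)
        assert detection_power(100, 0.01) < detection_power(100, 0.02)

    @pytest.mark.parametrize("p, target, expected", [
        (0.5, 0.8, 3),        # 1 - 0.5^3 = 0.875 >= 0.8 > 1 - 0.5^2
        (0.001, 0.8, 1609),
    ])
    def test_min_sample_size_reference_points(self, p, target, expected):
        assert min_sample_size(PowerSpec(power_target=target,
                                         true_frequency=p)) == expected

    def test_closed_form_equals_linear_scan(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            p = float(rng.uniform(1e-4, 0.5))
            target = float(rng.uniform(0.5, 0.99))
            n = min_sample_size(PowerSpec(power_target=target,
                                          true_frequency=p))
            grid = np.arange(1, n + 2)
            powers = -np.expm1(grid * np.log1p(-p))
            first = int(grid[np.argmax(powers >= target)])
            assert n == first

    def test_extreme_target_hits_cap(self):
        with pytest.raises(OverflowError):
            min_sample_size(PowerSpec(power_target=1 - 1e-12,
                                      true_frequency=1e-6), cap=10 ** 6)

    def test_sample_size_table_shape(self):
        tab = sample_size_table((0.001, 0.01), (0.8, 0.9))
        assert len(tab) == 4
        assert tab["min_n"].min() >= 1
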
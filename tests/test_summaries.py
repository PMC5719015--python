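"""Descriptive statistics: frequencies, synchrony, wind rose, correlation."""

import math
from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmgf.records import DIRECTIONS, ScreeningRecord, WeatherRecord
from pmgf.summaries import (CorrelationResult, UndefinedFrequencyError,
                            UndefinedSynchronyError, correlate_pmgf_wind,
                            flowering_synchrony, gene_flow_frequency,
                            per_direction_frequency,
                            pooled_frequency_by_distance, sector_of,
                            wind_parameter_by_arm, wind_rose)


class TestGeneFlowFrequency:
    @pytest.mark.parametrize("y, n, rounded", [
        (1546, 2591, 0.60),   # published near-source frequency, year 1
        (2218, 5198, 0.43),   # published 0.1 m frequency, year 2
        (326, 10047, 0.03),   # published 50 m frequency, year 2
        (0, 100, 0.0),
    ])
    def test_matches_published_rounding(self, y, n, rounded):
        assert round(gene_flow_frequency(y, n), 2) == rounded

    def test_zero_screened_is_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            gene_flow_frequency(0, 0)


def _records_at(year, distance, counts):
    return [ScreeningRecord(year, d, distance, n, y)
            for d, (n, y) in zip(DIRECTIONS, counts)]


class TestPooledFrequency:
    def test_pools_counts_before_dividing(self):
        counts = [(100, 10), (200, 90), (100, 0), (50, 25),
                  (100, 10), (100, 10), (100, 10), (100, 10)]
        recs = _records_at(2014, 4.0, counts)
        table = pooled_frequency_by_distance(recs, 2014)
        pooled = sum(y for _, y in counts) / sum(n for n, _ in counts)
        assert table["frequency"].iloc[0] == pytest.approx(pooled)
        mean_ratios = np.mean([y / n for n, y in counts])
        table2 = pooled_frequency_by_distance(recs, 2014,
                                              method="mean_of_ratios")
        assert table2["frequency"].iloc[0] == pytest.approx(mean_ratios)
        assert pooled != pytest.approx(mean_ratios)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(0, 500)),
                    min_size=8, max_size=8))
    def test_pooled_equals_frequency_of_summed_counts(self, raw):
        counts = [(n, min(y, n)) for n, y in raw]
        recs = _records_at(2015, 10.0, counts)
        table = pooled_frequency_by_distance(recs, 2015)
        assert table["frequency"].iloc[0] == pytest.approx(
            gene_flow_frequency(sum(y for _, y in counts),
                                sum(n for n, _ in counts)), abs=1e-15)

    def test_first_year_point_one_metre_cell_excluded_by_default(self):
        recs = (_records_at(2014, 0.1, [(10, 5)] * 8)
                + _records_at(2014, 1.0, [(10, 2)] * 8))
        assert pooled_frequency_by_distance(recs, 2014)[
            "distance_m"].tolist() == [1.0]
        full = pooled_frequency_by_distance(recs, 2014, exclusions=())
        assert full["distance_m"].tolist() == [0.1, 1.0]


class TestFloweringSynchrony:
    def test_perfect_synchrony_in_both_conventions(self):
        assert flowering_synchrony([60, 60, 60], 60, "receptor_over_donor") == pytest.approx(100.0)
        assert flowering_synchrony([60, 60, 60], 60, "donor_over_receptor") == pytest.approx(1.0)

    def test_hand_computed_average(self):
        # (25/50 + 50/50 + 75/50 + 50/50) / 4 * 100 = 100
        assert flowering_synchrony([25, 50, 75, 50], 50, "receptor_over_donor") == \
            pytest.approx(100.0)

    def test_station_order_invariance(self):
        a = flowering_synchrony([10, 40, 90], 50, "receptor_over_donor")
        b = flowering_synchrony([90, 10, 40], 50, "receptor_over_donor")
        assert a == pytest.approx(b)

    def test_capping_limits_each_station(self):
        assert flowering_synchrony([100], 50, "receptor_over_donor") == pytest.approx(200.0)
        assert flowering_synchrony([100], 50, "receptor_over_donor", cap=True) == \
            pytest.approx(100.0)
        assert flowering_synchrony([25], 50, "donor_over_receptor", cap=True) == \
            pytest.approx(1.0)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedSynchronyError):
            flowering_synchrony([50], 0, "receptor_over_donor")
        with pytest.raises(UndefinedSynchronyError):
            flowering_synchrony([0, 50], 40, "donor_over_receptor")


def _stream(dirs_deg, speeds=None):
    speeds = speeds or [1.0] * len(dirs_deg)
    return [WeatherRecord(datetime(2014, 8, 1, i % 24), 20, 0, 50, s, d)
            for i, (d, s) in enumerate(zip(dirs_deg, speeds))]


class TestWindRose:
    def test_single_sector_stream(self):
        rose = wind_rose(_stream([180.0] * 10))
        by = {s.sector: s for s in rose}
        assert by["S"].frequency_pct == pytest.approx(100.0)
        assert sum(s.frequency_pct for s in rose) == pytest.approx(100.0)

    def test_boundary_angle_goes_clockwise_next(self):
        assert sector_of(22.5) == "NE"
        assert sector_of(22.4999) == "N"
        assert sector_of(337.5) == "N"
        assert sector_of(337.4999) == "NW"

    def test_frequencies_sum_to_100_and_wind_run_definition(self):
        rng = np.random.default_rng(0)
        stream = _stream(rng.uniform(0, 360, 500).tolist(),
                         rng.gamma(2, 1.0, 500).tolist())
        rose = wind_rose(stream)
        assert sum(s.frequency_pct for s in rose) == pytest.approx(100.0,
                                                                   abs=1e-9)
        for s in rose:
            assert s.wind_run == pytest.approx(
                s.mean_speed_ms * s.frequency_pct / 100.0)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            wind_rose([])


class TestCorrelation:
    def _freq_table(self, freqs, distance=10.0):
        recs = _records_at(2014, distance,
                           [(1000, int(round(1000 * f))) for f in freqs])
        return per_direction_frequency(recs, 2014)

    def test_proportional_vectors_give_unit_correlation(self):
        rose = wind_rose(_stream(
            np.repeat([0, 45, 90, 135, 180, 225, 270, 315], 2).tolist(),
            np.repeat([1, 2, 3, 4, 5, 6, 7, 8], 2).tolist()))
        arm = wind_parameter_by_arm(rose, "speed", mapping="sector")
        freqs = [arm[d] / 20 for d in DIRECTIONS]
        res = correlate_pmgf_wind(self._freq_table(freqs), rose,
                                  "speed", mapping="sector")[0]
        assert res.r == pytest.approx(1.0, abs=1e-9)
        anti = correlate_pmgf_wind(self._freq_table([0.5 - f for f in freqs]),
                                   rose, "speed", mapping="sector")[0]
        assert anti.r == pytest.approx(-1.0, abs=1e-9)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(1)
        rose = wind_rose(_stream(rng.uniform(0, 360, 300).tolist(),
                                 rng.gamma(2, 1.2, 300).tolist()))
        freqs = rng.uniform(0.01, 0.5, 8)
        res = correlate_pmgf_wind(self._freq_table(freqs), rose, "run")[0]
        arm = wind_parameter_by_arm(rose, "run", "downwind")
        x = np.array([round(1000 * f) / 1000 for f in freqs])
        w = np.array([arm[d] for d in DIRECTIONS])
        r_hand = (np.sum((x - x.mean()) * (w - w.mean()))
                  / math.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((w - w.mean()) ** 2)))
        assert res.r == pytest.approx(r_hand, abs=1e-12)

    def test_downwind_mapping_uses_opposite_sector(self):
        rose = wind_rose(_stream([180.0] * 8, [2.0] * 8))  # all wind FROM S
        arm = wind_parameter_by_arm(rose, "frequency", "downwind")
        assert arm["N"] == pytest.approx(100.0)
        assert arm["S"] == pytest.approx(0.0)

    def test_zero_variance_flagged_not_nan_silent(self):
        rose = wind_rose(_stream(np.linspace(0, 359, 64).tolist()))
        res = correlate_pmgf_wind(self._freq_table([0.2] * 8), rose, "run")[0]
        assert isinstance(res, CorrelationResult)
        assert not res.defined

    def test_null_kernel_gives_uniform_p_values(self):
        """Direction-independent PMGF + wind: p-values ~ Uniform(0,1)."""
        from scipy import stats
        rng = np.random.default_rng(8)
        rose = wind_rose(_stream(rng.uniform(0, 360, 400).tolist(),
                                 rng.gamma(2, 1.0, 400).tolist()))
        pvals = []
        for _ in range(200):
            freqs = rng.uniform(0.05, 0.5, 8)
            res = correlate_pmgf_wind(self._freq_table(freqs), rose, "run")[0]
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3
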
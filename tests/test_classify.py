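import itertools

import numpy as np
import pytest

from cropcycles import (
    AlgorithmConfig,
    PhenoFit,
    assign_intensity,
    classify_aligned,
    classify_pixel_year,
    filter_peaks,
    find_extrema,
    pair_valleys,
    qc_code,
    qc_conditions,
)
from cropcycles.classify import PeakRecord, _perturbed_intensity
from cropcycles.phenofit import Extremum
from cropcycles.preprocess import AlignedSeries


def record(peak_value=0.55, peak_t=150.0, left=(30.0, 0.10), right=(250.0, 0.15)):
    return PeakRecord(
        peak=Extremum(time_days=peak_t, value=peak_value, kind="max"),
        left_valley=left,
        right_valley=right,
        depth_left=peak_value - left[1],
        depth_right=peak_value - right[1],
        duration_left=peak_t - left[0],
        duration_right=right[0] - peak_t,
    )


def flat_aligned(n_interp=0, frac_ok=1.0):
    return AlignedSeries(
        year=2002,
        times=np.arange(23) * 16.0,
        values=np.full(23, 0.3),
        n_interpolated_in_year=n_interp,
        frac_acceptable_in_year=frac_ok,
    )


class TestPairValleys:
    def test_single_maximum_gets_endpoint_valleys(self):
        # downward parabola: one interior max, no interior minima
        fit = PhenoFit(coeffs=[0.1, 2.0, -2.0, 0, 0, 0, 0], span_days=352.0)
        ex = find_extrema(fit)
        recs = pair_valleys(ex, fit)
        assert len(recs) == 1
        assert recs[0].left_valley == (0.0, pytest.approx(0.1))
        assert recs[0].right_valley == (352.0, pytest.approx(0.1))

    def test_shared_minimum_between_two_peaks(self):
        extrema = [
            Extremum(100.0, 0.6, "max"),
            Extremum(180.0, 0.2, "min"),
            Extremum(260.0, 0.7, "max"),
        ]
        fit = PhenoFit(coeffs=[0.1, 0, 0, 0, 0, 0, 0], span_days=352.0)
        recs = pair_valleys(extrema, fit)
        assert recs[0].right_valley == (180.0, 0.2)
        assert recs[1].left_valley == (180.0, 0.2)
        assert recs[0].left_valley[0] == 0.0
        assert recs[1].right_valley[0] == 352.0

    def test_three_maxima_endpoints_only_on_outer_flanks(self):
        extrema = [
            Extremum(40.0, 0.5, "max"),
            Extremum(100.0, 0.2, "min"),
            Extremum(176.0, 0.6, "max"),
            Extremum(250.0, 0.25, "min"),
            Extremum(320.0, 0.55, "max"),
        ]
        fit = PhenoFit(coeffs=[0.15, 0, 0, 0, 0, 0, 0], span_days=352.0)
        recs = pair_valleys(extrema, fit)
        valley_times = [(r.left_valley[0], r.right_valley[0]) for r in recs]
        assert valley_times == [(0.0, 100.0), (100.0, 250.0), (250.0, 352.0)]


class TestFilterPeaks:
    def test_good_peak_passes_all_three(self, config):
        recs = filter_peaks([record()], config)
        assert len(recs) == 1
        r = recs[0]
        assert r.passes_amplitude and r.passes_depth and r.passes_duration

    def test_low_amplitude_rejected_by_amplitude_only(self, config):
        r = record(peak_value=0.30, left=(30.0, 0.10), right=(250.0, 0.10))
        assert filter_peaks([r], config) == []
        assert not r.passes_amplitude
        assert r.passes_depth and r.passes_duration

    def test_shallow_depth_rejected_by_depth_only(self, config):
        r = record(peak_value=0.50, left=(30.0, 0.10), right=(250.0, 0.495))
        assert filter_peaks([r], config) == []
        assert not r.passes_depth
        assert r.passes_amplitude and r.passes_duration

    def test_short_season_rejected_by_duration_only(self, config):
        # whole cycle spans 60 days: valleys at 120 and 180 around a 150-day peak
        r = record(peak_value=0.50, peak_t=150.0, left=(120.0, 0.1), right=(180.0, 0.1))
        assert filter_peaks([r], config) == []
        assert not r.passes_duration
        assert r.passes_amplitude and r.passes_depth

    def test_min_side_rule_rejects_one_short_side(self):
        cfg = AlgorithmConfig(duration_rule="min_side")
        # one valley 60 days from the peak: span would pass, min side fails
        r = record(peak_value=0.50, peak_t=150.0, left=(30.0, 0.1), right=(210.0, 0.1))
        assert filter_peaks([r], cfg) == []
        assert not r.passes_duration
        assert filter_peaks([record(peak_value=0.50, peak_t=150.0, left=(30.0, 0.1), right=(210.0, 0.1))]) != []

    def test_either_depth_rule_accepts_one_deep_side(self):
        cfg = AlgorithmConfig(depth_rule="either")
        r = record(peak_value=0.50, left=(30.0, 0.10), right=(250.0, 0.495))
        assert filter_peaks([r], cfg) == [r]

    def test_raising_thresholds_never_increases_intensity(self, noisy_pixel):
        base = AlgorithmConfig()
        series, _ = noisy_pixel(2, seed=5)
        i0 = classify_pixel_year(series, 2002, base).intensity
        for kwargs in (
            {"peak_min_evi": 0.5},
            {"min_peak_valley_depth": 0.2},
            {"min_peak_valley_duration_days": 150.0},
        ):
            stricter = AlgorithmConfig(**kwargs)
            assert classify_pixel_year(series, 2002, stricter).intensity <= i0


class TestAssignIntensity:
    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 1), (2, 2), (3, 3), (5, 3)])
    def test_count_capped_at_three(self, n, expected):
        assert assign_intensity([object()] * n) == expected


class TestQcConditions:
    def test_clean_pixel_meets_all_conditions(self, config):
        # exact polynomial data: delta = 0 cannot flip the decision
        fit = PhenoFit(coeffs=[0.1, 2.0, -2.0, 0, 0, 0, 0], span_days=352.0)
        flags = qc_conditions(flat_aligned(), fit, intensity=1, config=config)
        assert flags == (True, True, True)

    def test_half_unacceptable_year_fails_condition_one(self, config):
        fit = PhenoFit(coeffs=[0.3, 0, 0, 0, 0, 0, 0], span_days=352.0)
        flags = qc_conditions(flat_aligned(frac_ok=10 / 23), fit, 0, config)
        assert flags[0] is False

    def test_twelve_interpolated_fails_condition_two(self, config):
        fit = PhenoFit(coeffs=[0.3, 0, 0, 0, 0, 0, 0], span_days=352.0)
        assert qc_conditions(flat_aligned(n_interp=12), fit, 0, config)[1] is False
        assert qc_conditions(flat_aligned(n_interp=11), fit, 0, config)[1] is True

    def test_marginal_peak_with_delta_fails_condition_three(self, config):
        # parabola peaking at 0.355: lowering by delta=0.02 crosses the 0.35 bar
        fit = PhenoFit(coeffs=[0.23, 0.5, -0.5, 0, 0, 0, 0], span_days=352.0, delta=0.02)
        assert fit.value_at_u(0.5) == pytest.approx(0.355)
        flags = qc_conditions(flat_aligned(), fit, intensity=1, config=config)
        assert flags[2] is False

    def test_perturbation_drops_marginal_peak(self, config):
        recs = [record(peak_value=0.355, left=(30.0, 0.2), right=(250.0, 0.2))]
        assert _perturbed_intensity(recs, delta=0.02, config=config) == 0
        assert _perturbed_intensity(recs, delta=0.0, config=config) == 1


class TestQcCode:
    @pytest.mark.parametrize("flags", list(itertools.product([False, True], repeat=3)))
    def test_code_counts_failed_conditions(self, flags):
        assert qc_code(flags) == 3 - sum(flags)

    def test_named_grades(self):
        assert qc_code((True, True, True)) == 0  # best
        assert qc_code((True, False, True)) == 1  # good
        assert qc_code((False, False, False)) == 3  # poor


class TestEndToEnd:
    def test_identical_input_identical_result(self, noisy_pixel):
        series, _ = noisy_pixel(2, seed=77)
        r1 = classify_pixel_year(series, 2002)
        r2 = classify_pixel_year(series, 2002)
        assert r1 == r2

    def test_intensity_equals_min_of_count_and_cap(self, clean_pixel):
        for k in range(4):
            series, truth = clean_pixel(k, seed=k)
            res = classify_pixel_year(series, 2002)
            assert res.intensity == min(res.n_valid_peaks, 3) == truth
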
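"""Consumption, growth, per-cell rate and coupling-regression behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n2oresp import (
    IncubationSeries,
    VesselConditions,
    analyze_series,
    consumption,
    coupling_regression,
    exponential_growth_rate,
    fit_growth_rate,
    mean_rate_per_cell,
    rate_enhancement,
)
from n2oresp.errors import (
    ArgumentError,
    ConfigurationError,
    DegenerateFitError,
    ValidationError,
)
from n2oresp.kinetics import od_to_cells, trapezoidal_mean


class TestConsumption:
    @pytest.mark.parametrize(
        "initial, final, expected",
        [(83.81, 0.58, 83.23), (105.99, 63.13, 42.86), (89.63, 0.77, 88.86)],
    )
    def test_worked_endpoint_values(self, initial, final, expected):
        assert consumption(initial, final) == pytest.approx(expected, abs=1e-9)

    def test_no_change_is_zero(self):
        assert consumption(7.7, 7.7) == 0.0

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    @settings(derandomize=True)
    def test_antisymmetric(self, a, b):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert consumption(a, b) == -consumption(b, a)

    def test_net_production_warns_but_returns(self):
        with pytest.warns(UserWarning, match="net production"):
            assert consumption(1.0, 3.0) == -2.0


class TestGrowthRate:
    def test_worked_od_endpoints(self):
        # 0.0675 -> 0.1925 over 24 h is 0.0437 h-1 at 4 decimals
        assert round(exponential_growth_rate(0.0675, 0.1925, 24.0), 4) == 0.0437

    @given(st.floats(0.01, 2.0), st.floats(0.1, 100.0))
    @settings(derandomize=True)
    def test_doubling_identity(self, od, interval):
        assert exponential_growth_rate(od, 2 * od, interval) == pytest.approx(
            math.log(2) / interval, rel=1e-12
        )

    def test_fit_recovers_noiseless_exponential(self):
        t = np.linspace(0.0, 24.0, 13)
        od = 0.05 * np.exp(0.05 * t)
        mu, _, r2 = fit_growth_rate(t, od)
        assert mu == pytest.approx(0.05, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_and_fit_agree_on_noiseless_series(self):
        t = np.array([0.0, 24.0])
        od = 0.0675 * np.exp(0.0437 * t)
        mu_fit, _, _ = fit_growth_rate(t, od)
        mu_two = exponential_growth_rate(od[0], od[1], 24.0)
        assert mu_fit == pytest.approx(mu_two, rel=1e-10)

    def test_rejects_nonpositive_od(self):
        with pytest.raises(ArgumentError):
            exponential_growth_rate(0.0, 0.1, 24.0)

    def test_fit_needs_time_variance(self):
        with pytest.raises(DegenerateFitError):
            fit_growth_rate([1.0, 1.0], [0.1, 0.2])


class TestPerCellRate:
    def test_constructed_identity(self):
        # divisor chosen so the rate is exactly 1e-9 µmol h-1 cell-1
        cells = 78.31 / 24.0 * 1e9
        assert mean_rate_per_cell(78.31, 24.0, cells) == pytest.approx(1e-9, rel=1e-12)

    @given(st.floats(1.0, 100.0), st.floats(1.1, 10.0))
    @settings(derandomize=True)
    def test_inverse_scaling_with_cell_count(self, consumed, k):
        base = mean_rate_per_cell(consumed, 24.0, 1e9)
        assert mean_rate_per_cell(consumed, 24.0, k * 1e9) == pytest.approx(
            base / k, rel=1e-9
        )

    def test_od_conversion_requires_factor(self):
        with pytest.raises(ConfigurationError):
            od_to_cells(0.1, None, 30.0)

    def test_od_conversion(self):
        assert od_to_cells(0.1, 8e8, 30.0) == pytest.approx(0.1 * 8e8 * 30.0)

    def test_trapezoidal_mean_of_linear_series_is_midpoint(self):
        t = np.array([0.0, 12.0, 24.0])
        v = np.array([1.0, 2.0, 3.0])
        assert trapezoidal_mean(t, v) == pytest.approx(2.0)


class TestCouplingRegression:
    def test_collinear_input(self):
        donor = [0.0, 10.0, 20.0, 30.0]
        n2o = [0.0, 8.8, 17.6, 26.4]
        slope, intercept, r2 = coupling_regression(donor, n2o)
        assert slope == pytest.approx(0.88, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == 1.0

    def test_noisy_coupled_series_recovers_ratio(self):
        rng = np.random.default_rng(42)
        donor = np.linspace(0.0, 94.6, 12)
        n2o = 0.88 * donor + rng.normal(0.0, 0.01 * 83.0, donor.size)
        slope, _, r2 = coupling_regression(donor, n2o)
        assert slope == pytest.approx(0.88, rel=0.05)
        assert r2 > 0.95

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        donor = np.linspace(0.0, 50.0, 9)
        n2o = 2.07 * donor + rng.normal(0.0, 0.5, donor.size)
        perm = rng.permutation(donor.size)
        assert coupling_regression(donor, n2o) == pytest.approx(
            coupling_regression(donor[perm], n2o[perm])
        )

    def test_r2_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        donor = np.linspace(0.0, 10.0, 8)
        n2o = rng.normal(5.0, 3.0, donor.size)  # uncoupled
        *_, r2 = coupling_regression(donor, n2o)
        assert 0.0 <= r2 <= 1.0

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(DegenerateFitError):
            coupling_regression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateFitError):
            coupling_regression([1.0, 2.0], [1.0, 2.0])


class TestRateEnhancement:
    def test_nitrate_treatment_fold_change(self):
        assert round(rate_enhancement(1.53e-8, 4.39e-9), 1) == 3.5

    def test_ammonium_treatment_fold_change(self):
        assert round(rate_enhancement(1.39e-8, 4.39e-9), 1) == 3.2

    def test_identity(self):
        assert rate_enhancement(5e-9, 5e-9) == 1.0

    def test_rejects_nonpositive_control(self):
        with pytest.raises(ArgumentError):
            rate_enhancement(1e-9, 0.0)


def _series(times, n2o, od, donor, vessel=None):
    return IncubationSeries(
        times=np.asarray(times), total_n2o=np.asarray(n2o),
        od600=np.asarray(od), donor=np.asarray(donor),
        vessel=vessel,
    )


class TestIncubationSeriesAndAnalysis:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValidationError):
            _series([0.0, 2.0, 2.0], [3, 2, 1], [0.1] * 3, [5, 4, 3])

    def test_rejects_negative_amounts(self):
        with pytest.raises(ValidationError):
            _series([0.0, 1.0], [-1.0, 0.5], [0.1, 0.1], [1.0, 0.5])

    def test_endpoint_analysis_matches_direct_computation(self):
        s = _series([0.0, 24.0], [83.81, 0.58], [0.0675, 0.1925], [173.45, 78.84])
        report = analyze_series(s)
        assert report.n2o_consumed == pytest.approx(83.23)
        assert report.donor_consumed == pytest.approx(94.61)
        assert report.od_increase == pytest.approx(0.125)
        assert round(report.growth_rate, 4) == 0.0437
        assert report.coupling_r2 is None  # two points cannot support a fit

    def test_missing_n2o_points_excluded_but_od_kept(self):
        s = _series(
            [0.0, 12.0, 24.0],
            [80.0, np.nan, 10.0],
            [0.05, 0.10, 0.20],
            [100.0, np.nan, 50.0],
        )
        report = analyze_series(s)
        assert report.n2o_consumed == pytest.approx(70.0)
        mu, _, _ = fit_growth_rate([0.0, 12.0, 24.0], [0.05, 0.10, 0.20])
        assert report.growth_rate == pytest.approx(mu)

    def test_per_cell_rate_requires_conversion_and_vessel(self):
        s = _series(
            [0.0, 24.0], [83.81, 0.58], [0.0675, 0.1925], [173.45, 78.84],
            vessel=VesselConditions(),
        )
        without = analyze_series(s)
        assert without.mean_rate_per_cell is None
        with_factor = analyze_series(s, cells_per_ml_per_od=8e8)
        mean_cells = (0.0675 + 0.1925) / 2 * 8e8 * 30.0
        assert with_factor.mean_rate_per_cell == pytest.approx(
            83.23 / (24.0 * mean_cells), rel=1e-9
        )

    def test_retimestamping_invariance(self):
        times = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        n2o = np.array([80.0, 60.0, 35.0, 12.0, 2.0])
        od = np.array([0.05, 0.08, 0.12, 0.17, 0.19])
        donor = np.array([170.0, 147.0, 119.0, 93.0, 81.0])
        base = analyze_series(_series(times, n2o, od, donor))
        shifted = analyze_series(_series(times + 100.0, n2o, od, donor))
        assert shifted.n2o_consumed == base.n2o_consumed
        assert shifted.growth_rate == pytest.approx(base.growth_rate, rel=1e-12)
        assert shifted.coupling_slope == pytest.approx(base.coupling_slope, rel=1e-12)
        assert shifted.coupling_r2 == pytest.approx(base.coupling_r2, rel=1e-12)
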
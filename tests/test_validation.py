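"""Calibration, detection limits, recovery and percent-degradation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabkit.simulate import gen_calibration
from stabkit.validation import (
    LinearCalibration,
    fit_calibration,
    llod_lloq,
    percent_degradation,
    recovery_stats,
    summarize_accuracy_precision,
    summarize_robustness,
    summarize_stability,
)

LEVELS = np.array([1.0, 5.0, 10.0, 20.0, 40.0, 80.0, 100.0])


class TestCalibrationFit:
    def test_noiseless_line_recovered_exactly(self):
        cal = LinearCalibration().fit(LEVELS, 49940.0 * LEVELS + 31468.0)
        assert cal.slope_ == pytest.approx(49940.0, rel=1e-12)
        assert cal.intercept_ == pytest.approx(31468.0, rel=1e-9)
        assert cal.r_ == pytest.approx(1.0, abs=1e-12)
        assert cal.residual_sd_ == pytest.approx(0.0, abs=1e-6)

    def test_two_point_zero_intercept(self):
        cal = LinearCalibration().fit([1.0, 2.0], [10.0, 20.0])
        assert cal.slope_ == pytest.approx(10.0)
        assert cal.intercept_ == pytest.approx(0.0, abs=1e-12)
        assert cal.r_ == pytest.approx(1.0)

    def test_flat_response_breaks_limits_downstream(self):
        cal = LinearCalibration().fit(LEVELS, np.full_like(LEVELS, 100.0))
        assert cal.slope_ == 0.0
        with pytest.raises(ZeroDivisionError):
            cal.inverse_predict(100.0)

    def test_single_level_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|distinct"):
            LinearCalibration().fit([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_fit_from_tidy_frame(self):
        df = gen_calibration(noise_sd_area=0.0)
        cal = fit_calibration(df)
        assert cal.r_ == pytest.approx(1.0)
        assert cal.n_ == 21


class TestDetectionLimits:
    def test_back_solved_sd_reproduces_reported_limit(self):
        llod, lloq = llod_lloq(19976.0, 49940.0)
        assert llod == pytest.approx(1.32, abs=0.005)

    def test_zero_sd(self):
        assert llod_lloq(0.0, 49940.0) == (0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        sd=st.floats(1e-6, 1e6), slope=st.floats(1e-3, 1e6)
    )
    def test_ratio_is_ten_over_three_point_three(self, sd, slope):
        llod, lloq = llod_lloq(sd, slope)
        assert lloq / llod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_scale_equivariance(self):
        d1, q1 = llod_lloq(100.0, 50.0)
        d2, q2 = llod_lloq(200.0, 50.0)
        d3, q3 = llod_lloq(100.0, 100.0)
        assert (d2, q2) == (2 * d1, 2 * q1)
        assert (d3, q3) == (d1 / 2, q1 / 2)

    def test_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            llod_lloq(10.0, 0.0)


class TestInversePrediction:
    def test_intercept_maps_to_zero(self):
        cal = LinearCalibration().fit(LEVELS, 49940.0 * LEVELS + 31468.0)
        assert cal.inverse_predict(31468.0) == pytest.approx(0.0, abs=1e-9)
        assert cal.inverse_predict(1030268.0) == pytest.approx(20.0, rel=1e-9)

    def test_round_trip_identity(self):
        cal = LinearCalibration().fit(LEVELS, 1234.5 * LEVELS - 77.0)
        c = np.array([0.5, 3.0, 42.0])
        assert cal.inverse_predict(cal.predict(c)) == pytest.approx(c, rel=1e-12)

    def test_negative_results_flagged(self):
        cal = LinearCalibration().fit(LEVELS, 49940.0 * LEVELS + 31468.0)
        c = cal.inverse_predict(1000.0)
        assert c < 0
        assert cal.flag(c)[0] == "negative"


class TestRecovery:
    def test_perfect_recovery(self):
        st_ = recovery_stats([20.0, 20.0, 20.0], 20.0)
        assert st_.mean_recovery == 100.0 and st_.rsd_pct == 0.0

    def test_reported_tablet_assay(self):
        # six determinations with mean 20.384 against nominal 20
        st_ = recovery_stats([20.384] * 6, 20.0)
        assert st_.mean_recovery == pytest.approx(101.92, abs=0.005)

    def test_hand_computed_rsd(self):
        st_ = recovery_stats([18.0, 22.0], 20.0)
        assert st_.mean_recovery == pytest.approx(100.0)
        assert st_.rsd_pct == pytest.approx(14.14, abs=0.005)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            recovery_stats([20.0], 0.0)


class TestPercentDegradation:
    @pytest.mark.parametrize(
        "ref, stressed, expected", [(1000, 1000, 0.0), (1000, 500, 50.0), (1000, 1008, -0.8)]
    )
    def test_examples(self, ref, stressed, expected):
        assert percent_degradation(ref, stressed) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(-50, 100), a=st.floats(1e-3, 1e9))
    def test_inverse_identity(self, p, a):
        assert percent_degradation(a, a * (1 - p / 100.0)) == pytest.approx(p, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_degradation(0.0, 10.0)


class TestSummaries:
    def test_identical_values_give_zero_rsd(self):
        df = pd.DataFrame(
            {"level": ["100"] * 3, "series": ["intra"] * 3, "found_ug_ml": [20.0] * 3}
        )
        out = summarize_accuracy_precision(df, {"100": 20.0})
        assert out.loc[0, "recovery_pct"] == 100.0 and out.loc[0, "rsd_pct"] == 0.0

    def test_three_spiking_levels_three_rows(self, rng):
        nominal = {"80": 16.0, "100": 20.0, "120": 24.0}
        rows = []
        for lvl, nom in nominal.items():
            for _ in range(6):
                rows.append(
                    {"level": lvl, "series": "intra", "found_ug_ml": nom * rng.normal(1.01, 0.008)}
                )
        out = summarize_accuracy_precision(pd.DataFrame(rows), nominal)
        assert len(out) == 3
        assert (out.recovery_pct.between(95, 107)).all()

    def test_robustness_keeps_condition_order(self):
        df = pd.DataFrame(
            {
                "condition": ["flow 0.9", "flow 0.9", "flow 1.1", "flow 1.1"],
                "found_ug_ml": [20.6, 20.6, 19.8, 19.8],
            }
        )
        out = summarize_robustness(df, 20.0)
        assert list(out.condition) == ["flow 0.9", "flow 1.1"]
        assert out.loc[0, "recovery_pct"] == pytest.approx(103.0)

    def test_stability_series_appends_mean_row(self):
        df = pd.DataFrame(
            {
                "time_h": np.repeat([0.0, 4.0, 8.0, 12.0, 24.0], 2),
                "found_ug_ml": 20.0 + np.tile([0.1, -0.1], 5),
            }
        )
        out = summarize_stability(df, 20.0)
        assert len(out) == 6  # 5 time points + mean
        assert np.isnan(out.iloc[-1].time_h)
        assert out.iloc[-1].recovery_pct == pytest.approx(100.0)
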
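"""Closed-form metric interconversions and their algebraic inverses."""

import math
import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

import tdtkit as tdt

zs = st.floats(min_value=1.0, max_value=10.0)
cts = st.floats(min_value=30.0, max_value=45.0)


class TestPredictTime:
    def test_anchor_identity(self, fly_curve):
        assert tdt.predict_time(fly_curve, 40.0) == pytest.approx(60.0)

    def test_forty_fold_extrapolation(self, anchored_truth):
        # (37 °C, 40 min) anchor: the same line passes through
        # (41 °C, 1 min) and (33 °C, 1600 min)
        assert tdt.predict_time(anchored_truth, 41.0) == pytest.approx(
            1.0, rel=1e-9
        )
        assert tdt.predict_time(anchored_truth, 33.0) == pytest.approx(
            1600.0, rel=1e-9
        )

    def test_halved_z_collapses_hot_side_prediction(self, anchored_truth):
        # misestimating z by -50% turns the 1-min prediction at 41 °C
        # into 1.5 s
        z_half = anchored_truth.z / 2.0
        c = tdt.TDTCurve(
            z=z_half, ct_ref=37.0 + z_half * math.log10(40.0 / 60.0)
        )
        assert tdt.predict_time(c, 41.0) * 60.0 == pytest.approx(1.5, rel=1e-9)

    @given(zs, cts, st.floats(min_value=25, max_value=50),
           st.floats(min_value=25, max_value=50))
    def test_log_linear_in_temperature(self, z, ct, T1, T2):
        c = tdt.TDTCurve(z=z, ct_ref=ct)
        lhs = math.log10(tdt.predict_time(c, T1)) - math.log10(
            tdt.predict_time(c, T2)
        )
        assert lhs == pytest.approx((T2 - T1) / z, rel=1e-9, abs=1e-12)


class TestPredictSctmax:
    def test_reference_duration_returns_anchor(self, fly_curve):
        assert tdt.predict_sctmax(fly_curve, 60.0) == fly_curve.ct_ref

    def test_moderate_extrapolation(self, anchored_truth):
        # 40 min -> 60 min is mild extrapolation: sCT_max(1 h) = 36.560 °C
        assert tdt.predict_sctmax(anchored_truth, 60.0) == pytest.approx(
            36.560, abs=5e-4
        )

    def test_z_misestimation_barely_moves_sctmax_1h(self, anchored_truth):
        # z +/- 50% with the same (37 °C, 40 min) anchor: the 1-h estimate
        # moves by less than 0.22 °C
        true_sct = tdt.predict_sctmax(anchored_truth, 60.0)
        for f in (0.5, 1.5):
            z = f * anchored_truth.z
            c = tdt.TDTCurve(z=z, ct_ref=37.0 + z * math.log10(40.0 / 60.0))
            assert abs(tdt.predict_sctmax(c, 60.0) - true_sct) < 0.22

    def test_nonpositive_duration(self, fly_curve):
        with pytest.raises(tdt.TDTValidationError):
            tdt.predict_sctmax(fly_curve, 0.0)

    @given(zs, cts, st.floats(min_value=0.1, max_value=1e4))
    def test_inverse_of_predict_time(self, z, ct, duration):
        c = tdt.TDTCurve(z=z, ct_ref=ct)
        T = tdt.predict_sctmax(c, duration)
        assert tdt.predict_time(c, T) == pytest.approx(duration, rel=1e-10)


class TestRampOutcome:
    def test_hand_computed_outcomes(self, fly_curve):
        # k*15 = 6 ln10 makes the exponential term exactly 1e6
        out = tdt.predict_ramp_outcome(fly_curve, t0=25.0, rate=0.1)
        assert out.dctmax == pytest.approx(41.856, abs=5e-4)
        assert out.t_ld == pytest.approx(168.56, abs=5e-3)
        assert out.dctmax == out.t0 + out.rate * out.t_ld  # exact linearity

    def test_slower_ramps_knock_down_cooler(self, fly_curve):
        dct = [
            tdt.predict_ramp_outcome(fly_curve, 25.0, b).dctmax
            for b in (0.05, 0.1, 0.25)
        ]
        assert dct[0] == pytest.approx(41.10, abs=5e-3)
        assert dct[2] == pytest.approx(42.85, abs=5e-3)
        assert dct[0] < dct[1] < dct[2]

    def test_vanishing_rate_limit(self, fly_curve):
        out = tdt.predict_ramp_outcome(fly_curve, 25.0, 1e-12)
        assert out.dctmax == pytest.approx(25.0, abs=1e-3)

    def test_t_ld_decreasing_in_rate(self, fly_curve):
        t = [
            tdt.predict_ramp_outcome(fly_curve, 25.0, b).t_ld
            for b in (0.05, 0.1, 0.25)
        ]
        assert t[0] > t[1] > t[2]

    def test_dctmax_increasing_in_t_ref(self):
        base = tdt.TDTCurve(z=2.5, ct_ref=40.0, t_ref=60.0)
        longer = tdt.TDTCurve(z=2.5, ct_ref=40.0, t_ref=120.0)
        assert (
            tdt.predict_ramp_outcome(longer, 25.0, 0.1).dctmax
            > tdt.predict_ramp_outcome(base, 25.0, 0.1).dctmax
        )

    def test_rate_validation(self, fly_curve):
        with pytest.raises(tdt.TDTValidationError):
            tdt.predict_ramp_outcome(fly_curve, 25.0, 0.0)


class TestSctmaxFromRamp:
    def test_inverse_of_forward(self, fly_curve):
        out = tdt.predict_ramp_outcome(fly_curve, 25.0, 0.1)
        back = tdt.sctmax_from_ramp(out.dctmax, 25.0, 0.1, z=2.5, t_ref=60.0)
        assert back == pytest.approx(40.0, abs=1e-9)

    @given(zs, cts, st.floats(min_value=20, max_value=29),
           st.floats(min_value=0.01, max_value=1.0))
    def test_round_trip_randomized(self, z, ct, t0, rate):
        c = tdt.TDTCurve(z=z, ct_ref=ct)
        out = tdt.predict_ramp_outcome(c, t0, rate)
        back = tdt.sctmax_from_ramp(out.dctmax, t0, rate, z=z, t_ref=60.0)
        assert back == pytest.approx(ct, abs=1e-9)

    def test_ramp_ending_at_start_rejected(self):
        with pytest.raises(tdt.TDTValidationError):
            tdt.sctmax_from_ramp(25.0, 25.0, 0.1, z=2.5)

    def test_ramp_ending_below_baseline_rejected(self):
        with pytest.raises(tdt.InconsistentInputError):
            tdt.sctmax_from_ramp(26.0, 25.0, 0.1, z=2.5, tc_star=27.0)


class TestHarmonize:
    def test_reference_duration_is_anchor(self, fly_curve):
        obs = tdt.gen_static_obs(fly_curve, [37.0, 39.0, 41.0])
        fit = tdt.fit_static(obs, t_ref=60.0)
        h = tdt.harmonize_to_reference(fit, 60.0)
        assert h.sctmax == pytest.approx(fit.curve.ct_ref)
        assert h.method == "static-ols"

    def test_assumed_z_fit_is_flagged(self):
        fit = tdt.curve_from_single(
            tdt.StaticObservation(temp=37.0, time=40.0),
            assumed_z=4.0 / math.log10(40.0),
        )
        h = tdt.harmonize_to_reference(fit, 60.0)
        assert h.sctmax == pytest.approx(36.560, abs=5e-4)
        assert "assumed-z" in h.flags


class TestExtrapolationWarnings:
    def test_prediction_outside_span_warns(self, fly_curve):
        obs = tdt.gen_static_obs(fly_curve, [38.0, 40.0, 42.0])
        fit = tdt.fit_static(obs)
        with pytest.warns(tdt.ExtrapolationWarning):
            fit.predict_time(50.0)
        with pytest.warns(tdt.ExtrapolationWarning):
            fit.predict_sctmax(1e5)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit.predict_time(40.0)  # inside span: silent
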
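"""Injury-rate law, dose integration, and additivity arithmetic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tdtkit as tdt


def ramp_profile(t0, rate, t_end, n=2):
    ts = np.linspace(0.0, t_end, n)
    return tdt.TemperatureProfile(times=ts, temps=t0 + rate * ts)


def constant_profile(temp, t_end):
    return tdt.TemperatureProfile(
        times=np.array([0.0, t_end]), temps=np.array([temp, temp])
    )


class TestInjuryRate:
    def test_reciprocal_of_tolerance_time(self, fly_curve):
        assert tdt.injury_rate(fly_curve, 40.0) == pytest.approx(1.0 / 60.0)

    def test_rate_001_means_coma_in_100_min(self, fly_curve):
        temp = tdt.predict_sctmax(fly_curve, 100.0)
        assert tdt.injury_rate(fly_curve, temp) == pytest.approx(0.01, rel=1e-12)

    def test_exact_form_floor_and_convergence(self, fly_curve):
        tc = 30.0
        # at or below the floor the exact rate is zero
        assert tdt.injury_rate(fly_curve, 30.0, exact_tc=tc) == 0.0
        assert tdt.injury_rate(fly_curve, 25.0, exact_tc=tc) == 0.0
        # two decades above the floor the exact and simplified laws differ
        # by the factor (1 - 10^-2), i.e. 1%
        T = tc + 2 * fly_curve.z
        simple = tdt.injury_rate(fly_curve, T)
        exact = tdt.injury_rate(fly_curve, T, exact_tc=tc)
        assert exact / simple == pytest.approx(1.0 - 1e-2, rel=1e-12)


class TestIntegrateProfile:
    def test_constant_at_anchor_fails_at_t_ref(self, fly_curve):
        traj = tdt.integrate_profile(fly_curve, constant_profile(40.0, 120.0))
        assert traj.t_failure == pytest.approx(60.0, abs=traj.dt)
        assert tdt.time_to_dose(traj, 1.0) == pytest.approx(60.0, abs=traj.dt / 2)

    def test_linear_ramp_matches_closed_form(self, fly_curve):
        closed = tdt.predict_ramp_outcome(fly_curve, 25.0, 0.1)
        traj = tdt.integrate_profile(
            fly_curve, ramp_profile(25.0, 0.1, 1.5 * closed.t_ld)
        )
        assert tdt.time_to_dose(traj, 1.0) == pytest.approx(
            closed.t_ld, rel=2e-3
        )

    def test_benign_profile_accumulates_next_to_nothing(self, fly_curve):
        # 24 h at ct_ref - 10z: rate is 1e-10 of the anchor rate
        temp = fly_curve.ct_ref - 10 * fly_curve.z
        with pytest.warns(tdt.BelowRangeWarning):
            traj = tdt.integrate_profile(fly_curve, constant_profile(temp, 1440.0))
        assert traj.t_failure is None
        assert traj.final_dose == pytest.approx(1440.0 / 60.0 * 1e-10, rel=1e-9)
        with pytest.raises(tdt.DoseNotReached) as exc:
            tdt.time_to_dose(traj, 1.0)
        assert exc.value.final_dose == traj.final_dose

    def test_dose_monotone_and_starts_at_zero(self, fly_curve):
        traj = tdt.integrate_profile(fly_curve, ramp_profile(25.0, 0.1, 200.0))
        assert traj.dose[0] == 0.0
        assert np.all(np.diff(traj.dose) >= 0.0)

    def test_halving_dt_first_order_convergence(self, fly_curve):
        prof = ramp_profile(25.0, 0.1, 250.0)
        t1 = tdt.integrate_profile(fly_curve, prof, dt=1 / 6).t_failure
        t2 = tdt.integrate_profile(fly_curve, prof, dt=1 / 12).t_failure
        assert abs(t1 - t2) < 1 / 6

    def test_coarse_step_warns(self, fly_curve):
        prof = tdt.TemperatureProfile(
            times=np.array([0.0, 0.05, 60.0]),
            temps=np.array([39.0, 40.0, 40.0]),
        )
        with pytest.warns(tdt.RefinementWarning):
            tdt.integrate_profile(fly_curve, prof, dt=1 / 6)

    def test_supra_unity_dose_not_truncated(self, fly_curve):
        traj = tdt.integrate_profile(fly_curve, constant_profile(40.0, 90.0))
        assert traj.final_dose == pytest.approx(1.5, rel=1e-9)

    def test_exact_tc_far_below_matches_simplified(self, fly_curve):
        # floor > 3z below the stress range: trajectories agree to < 0.1%
        prof = constant_profile(40.0, 120.0)
        tc = 40.0 - 3.2 * fly_curve.z
        simple = tdt.time_to_dose(tdt.integrate_profile(fly_curve, prof), 1.0)
        exact = tdt.time_to_dose(
            tdt.integrate_profile(fly_curve, prof, exact_tc=tc), 1.0
        )
        assert exact == pytest.approx(simple, rel=1e-3)


class TestSegmentFractions:
    def test_worked_additivity_example(self, fly_curve):
        # 15 min where tolerance is 50 min spends 0.3 of the budget; the
        # remaining 0.7 at a temperature tolerated 300 min lasts 210 min
        t_hot = tdt.predict_sctmax(fly_curve, 50.0)
        t_mild = tdt.predict_sctmax(fly_curve, 300.0)
        rep = tdt.segment_fractions(
            fly_curve,
            [
                tdt.ExposureSegment(temp=t_hot, duration=15.0),
                tdt.ExposureSegment(temp=t_mild),
            ],
        )
        assert rep.fractions[0] == pytest.approx(0.3, rel=1e-12)
        assert rep.terminal_time == pytest.approx(210.0, rel=1e-12)

    def test_single_open_segment_at_anchor(self, fly_curve):
        rep = tdt.segment_fractions(fly_curve, [tdt.ExposureSegment(temp=40.0)])
        assert rep.terminal_time == pytest.approx(60.0)

    def test_overshoot_reports_crossing_not_error(self, fly_curve):
        rep = tdt.segment_fractions(
            fly_curve, [tdt.ExposureSegment(temp=40.0, duration=90.0)]
        )
        assert rep.total_dose == pytest.approx(1.5)
        assert rep.t_failure == pytest.approx(60.0)

    def test_terminal_with_no_budget_left_is_error(self, fly_curve):
        with pytest.raises(tdt.TDTValidationError):
            tdt.segment_fractions(
                fly_curve,
                [
                    tdt.ExposureSegment(temp=40.0, duration=90.0),
                    tdt.ExposureSegment(temp=38.0),
                ],
            )

    def test_open_segment_must_be_last_and_unique(self, fly_curve):
        with pytest.raises(tdt.TDTValidationError):
            tdt.segment_fractions(
                fly_curve,
                [tdt.ExposureSegment(40.0), tdt.ExposureSegment(38.0, 10.0)],
            )
        with pytest.raises(tdt.TDTValidationError):
            tdt.segment_fractions(
                fly_curve, [tdt.ExposureSegment(40.0), tdt.ExposureSegment(38.0)]
            )

    @given(
        st.floats(min_value=36.0, max_value=42.0),
        st.floats(min_value=1.0, max_value=100.0),
        st.integers(min_value=1, max_value=7),
    )
    def test_partition_additivity_is_exact(self, temp, duration, n_parts):
        c = tdt.TDTCurve(z=2.5, ct_ref=40.0)
        whole = tdt.segment_fractions(
            c, [tdt.ExposureSegment(temp, duration)]
        ).total_dose
        parts = tdt.segment_fractions(
            c,
            [tdt.ExposureSegment(temp, duration / n_parts)] * n_parts,
        ).total_dose
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_order_invariance_of_total_dose(self, fly_curve):
        segs = [
            tdt.ExposureSegment(39.5, 15.0),
            tdt.ExposureSegment(36.5, 90.0),
            tdt.ExposureSegment(38.0, 30.0),
        ]
        doses = {
            tdt.segment_fractions(fly_curve, list(p)).total_dose
            for p in itertools.permutations(segs)
        }
        assert max(doses) - min(doses) < 1e-12


class TestTimeToDose:
    def test_half_target_on_linear_growth(self, fly_curve):
        traj = tdt.integrate_profile(fly_curve, constant_profile(40.0, 120.0))
        assert tdt.time_to_dose(traj, 0.5) == pytest.approx(30.0, abs=traj.dt / 2)

    def test_target_must_be_positive(self, fly_curve):
        traj = tdt.integrate_profile(fly_curve, constant_profile(40.0, 10.0))
        with pytest.raises(tdt.TDTValidationError):
            tdt.time_to_dose(traj, 0.0)


class TestProfileValidation:
    def test_invariants(self):
        with pytest.raises(tdt.TDTValidationError):
            tdt.TemperatureProfile(times=np.array([0.0]), temps=np.array([40.0]))
        with pytest.raises(tdt.TDTValidationError):
            tdt.TemperatureProfile(
                times=np.array([0.0, 0.0]), temps=np.array([40.0, 41.0])
            )
        with pytest.raises(tdt.TDTValidationError):
            tdt.TemperatureProfile(
                times=np.array([0.0, 1.0]), temps=np.array([40.0])
            )
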
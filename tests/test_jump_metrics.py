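"""Flight-time formulas and contact/flight event detection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fatiguekit as fk
from fatiguekit.jumps import G_DEFAULT

BODY = fk.BodyParams(mass_kg=72.4)


class TestFormulas:
    """Closed-form parameter values frozen from symbolic evaluation."""

    def test_flight_height_worked_values(self):
        assert fk.flight_height(0.0) == 0.0
        assert fk.flight_height(0.5) == pytest.approx(0.3065625, rel=1e-12)
        assert fk.flight_height(0.40385502187692178, 9.81) == pytest.approx(0.2, rel=1e-12)

    def test_mean_power_worked_value(self):
        # symbolic evaluation of (m g^2/Tc)(Tf^2/4 + Tc|Tc+Tf|/pi - Tc^2/4)
        assert fk.mean_power(BODY, 0.25, 0.5) == pytest.approx(
            2969.7716381510140, rel=1e-9
        )

    def test_mean_power_zero_flight_limit(self):
        # Tf=0 collapses to m g^2 Tc (1/pi - 1/4)
        tc = 0.3
        expect = 72.4 * 9.81**2 * tc * (1 / math.pi - 0.25)
        assert fk.mean_power(BODY, tc, 0.0) == pytest.approx(expect, rel=1e-12)

    def test_mean_power_linear_in_mass(self):
        p1 = fk.mean_power(fk.BodyParams(70.0), 0.25, 0.5)
        p2 = fk.mean_power(fk.BodyParams(140.0), 0.25, 0.5)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_rsi_worked_value(self):
        assert fk.reactive_strength_index(0.0, 0.25) == 0.0
        assert fk.reactive_strength_index(0.3065625, 0.25) == pytest.approx(
            1.22625, rel=1e-9
        )
        h = 0.31
        assert fk.reactive_strength_index(h, 0.5) == pytest.approx(
            fk.reactive_strength_index(h, 0.25) / 2
        )

    def test_stiffness_worked_value(self):
        assert fk.leg_stiffness(BODY, 0.25, 0.5) == pytest.approx(
            15487.591786379095, rel=1e-9
        )

    def test_stiffness_linear_in_mass(self):
        k1 = fk.leg_stiffness(fk.BodyParams(60.0), 0.25, 0.5)
        k2 = fk.leg_stiffness(fk.BodyParams(120.0), 0.25, 0.5)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_stiffness_decreasing_in_tc_at_fixed_total(self):
        total = 0.75
        tcs = np.linspace(0.1, 0.5, 30)
        ks = [fk.leg_stiffness(BODY, tc, total - tc) for tc in tcs]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    @pytest.mark.parametrize(
        "func,args",
        [
            (fk.flight_height, (-0.1,)),
            (fk.mean_power, (BODY, 0.0, 0.5)),
            (fk.reactive_strength_index, (0.3, 0.0)),
            (fk.leg_stiffness, (BODY, 0.0, 0.5)),
            (fk.leg_stiffness, (BODY, 0.25, -0.1)),
        ],
    )
    def test_domain_errors(self, func, args):
        with pytest.raises(ValueError):
            func(*args)

    @given(
        tf=st.floats(0.2, 0.9),
        g=st.floats(9.0, 10.5),
    )
    def test_height_flight_time_round_trip(self, tf, g):
        assert fk.flight_time_from_height(fk.flight_height(tf, g), g) == pytest.approx(
            tf, rel=1e-12
        )

    @given(tf1=st.floats(0.2, 0.5), dtf=st.floats(0.01, 0.4))
    def test_height_monotone_in_flight_time(self, tf1, dtf):
        assert fk.flight_height(tf1 + dtf) > fk.flight_height(tf1)


class TestDetection:
    def test_constant_standing_gives_no_events(self):
        trace = fk.AccelTrace(fs_hz=100, t0=0.0, samples=np.ones(500))
        assert fk.detect_jump_events(trace) == []

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            fk.AccelTrace(fs_hz=100, t0=0.0, samples=np.array([]))

    def test_single_jump_recovered_within_one_sample(self):
        trace, truth = fk.simulate_jump_trace([fk.JumpSpec(0.25, 0.5)], fs_hz=100)
        events = fk.detect_jump_events(trace)
        assert len(events) == 1
        assert abs(events[0].tc_s - 0.25) <= 0.01
        assert abs(events[0].tf_s - 0.50) <= 0.01

    def test_fifteen_jumps_recovered_exactly_on_noiseless_trace(self, rng):
        specs = [
            fk.JumpSpec(tc, tf)
            for tc, tf in zip(rng.uniform(0.15, 0.6, 15), rng.uniform(0.3, 0.7, 15))
        ]
        trace, truth = fk.simulate_jump_trace(specs, fs_hz=100)
        events = fk.detect_jump_events(trace)
        assert len(events) == 15
        dt = 1.0 / trace.fs_hz
        for ev, tr in zip(events, truth):
            assert abs(ev.tc_s - tr.tc_s) <= dt + 1e-12
            assert abs(ev.tf_s - tr.tf_s) <= dt + 1e-12

    def test_detection_robust_to_noise(self):
        specs = [fk.JumpSpec(0.25, 0.5)] * 10
        trace, truth = fk.simulate_jump_trace(specs, fs_hz=100, noise_sd_g=0.03, seed=7)
        events = fk.detect_jump_events(trace)
        assert len(events) == 10
        for ev, tr in zip(events, truth):
            assert abs(ev.tf_s - tr.tf_s) <= 0.03

    def test_events_invariant_to_trace_start_time(self):
        trace, _ = fk.simulate_jump_trace([fk.JumpSpec(0.3, 0.45)] * 3, fs_hz=200)
        shifted = fk.AccelTrace(fs_hz=trace.fs_hz, t0=123.4, samples=trace.samples)
        ev0 = fk.detect_jump_events(trace)
        ev1 = fk.detect_jump_events(shifted)
        for a, b in zip(ev0, ev1):
            assert b.contact_start_s - a.contact_start_s == pytest.approx(123.4)
            assert a.tc_s == pytest.approx(b.tc_s)
            assert a.tf_s == pytest.approx(b.tf_s)

    def test_detector_idempotent_through_resynthesis(self, rng):
        specs = [
            fk.JumpSpec(tc, tf)
            for tc, tf in zip(rng.uniform(0.15, 0.5, 8), rng.uniform(0.3, 0.7, 8))
        ]
        trace, _ = fk.simulate_jump_trace(specs, fs_hz=100)
        first = fk.detect_jump_events(trace)
        respecs = [fk.JumpSpec(ev.tc_s, ev.tf_s) for ev in first]
        trace2, _ = fk.simulate_jump_trace(respecs, fs_hz=100)
        second = fk.detect_jump_events(trace2)
        assert len(second) == len(first)
        for a, b in zip(first, second):
            assert abs(a.tc_s - b.tc_s) <= 0.01 + 1e-12
            assert abs(a.tf_s - b.tf_s) <= 0.01 + 1e-12


class TestBoscoSummary:
    def _event(self, tc, tf, start=1.0):
        return fk.JumpEvent(start, start + tc, start + tc + tf)

    def test_single_event_matches_per_event_computation(self):
        res = fk.bosco_summary([self._event(0.25, 0.5)], BODY)
        assert res.n_jumps == 1
        assert res.tc_s == pytest.approx(0.25)
        assert res.h_max_m == pytest.approx(fk.flight_height(0.5))
        assert res.mean_power_w == pytest.approx(fk.mean_power(BODY, 0.25, 0.5))
        assert res.stiffness_nm == pytest.approx(fk.leg_stiffness(BODY, 0.25, 0.5))

    def test_identical_events_aggregate_like_one(self):
        one = fk.bosco_summary([self._event(0.3, 0.45)], BODY)
        ten = fk.bosco_summary([self._event(0.3, 0.45, start=i) for i in range(10)], BODY)
        assert ten.n_jumps == 10
        assert ten.h_max_m == pytest.approx(one.h_max_m)
        assert ten.mean_power_w == pytest.approx(one.mean_power_w)

    def test_outlier_excluded_by_validity_bounds(self):
        events = [self._event(0.3, 0.45, start=float(i)) for i in range(5)]
        events.append(self._event(0.3, 1.5, start=10.0))  # implausible flight
        res = fk.bosco_summary(events, BODY)
        assert res.n_jumps == 5
        assert res.tf_s == pytest.approx(0.45)

    def test_aggregate_height_identity(self):
        events = [self._event(0.2 + 0.02 * i, 0.4 + 0.03 * i, start=2.0 * i) for i in range(6)]
        res = fk.bosco_summary(events, BODY)
        assert res.h_max_m == pytest.approx(G_DEFAULT * res.tf_s**2 / 8, rel=1e-12)

    def test_all_events_filtered_is_an_error(self):
        with pytest.raises(ValueError, match="validity"):
            fk.bosco_summary([self._event(0.05, 1.5)], BODY)

    def test_empty_events_is_an_error(self):
        with pytest.raises(ValueError):
            fk.bosco_summary([], BODY)
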
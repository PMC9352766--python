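"""TENG-axon coupling: motion, drive terms, coupled stepping and runs."""

import dataclasses

import numpy as np
import pytest

from teng_neuron import (
    AxonConfig,
    ModelValidityError,
    MotionProfile,
    coupling_terms,
    detect_spikes,
    fixture_curve,
    gap_trajectory,
    resting_state,
    run_coupled,
    run_plain,
    step_coupled,
    step_plain,
)
from teng_neuron.cable_core import StimulusProtocol


class TestTrajectory:
    def test_static_device(self):
        prof = MotionProfile(v=0.0)
        for t in (0.0, 13.7, 500.0):
            x, dxdt = gap_trajectory(t, prof)
            assert x == prof.x_max
            assert dxdt == 0.0

    def test_initial_descent_kinematics(self):
        prof = MotionProfile(v=0.5, t_start=10.0)
        x, dxdt = gap_trajectory(12.0, prof)  # 2 ms after start
        assert x == pytest.approx(prof.x_max - 0.5e-3 * 2.0, rel=1e-12)
        assert dxdt == -0.5
        # before start: parked at x_max
        x0, v0 = gap_trajectory(5.0, prof)
        assert (x0, v0) == (prof.x_max, 0.0)

    def test_period_closed_form(self):
        prof = MotionProfile(v=0.4, x_min=1e-4, x_max=0.02)
        period = 2 * (prof.x_max - prof.x_min) / prof.v * 1e3
        assert prof.period_ms == pytest.approx(period, rel=1e-12)
        x, dxdt = gap_trajectory(period, prof)
        assert x == pytest.approx(prof.x_max, rel=1e-9)
        assert dxdt == prof.v  # incoming (ascending) one-sided velocity

    def test_bounds_and_speed_magnitude(self):
        prof = MotionProfile(v=0.3)
        t = np.linspace(0, 700, 7001)
        x, dxdt = gap_trajectory(t, prof)
        assert np.all(x >= prof.x_min - 1e-15)
        assert np.all(x <= prof.x_max + 1e-15)
        assert np.all(np.isin(np.abs(dxdt), [prof.v]))


class TestCouplingTerms:
    def test_zero_speed_zero_drive(self, flat_curve):
        ct = coupling_terms(0.01, 0.0, -60.0, flat_curve)
        assert ct.I_drive == 0.0

    def test_constant_fixture_zero_drive(self):
        curve = fixture_curve("constant")
        ct = coupling_terms(0.02, 0.7, -55.0, curve)
        assert ct.I_drive == 0.0

    def test_linear_voc_fixture_hand_value(self):
        # voc = 2e5 V/m * x, C/area = 2e-9 F/cm^2: I = -C dVoc/dx dx/dt
        # = 2e-9 F/cm^2 * 2e5 V/m * 0.005 m/s = 2e-6 A/cm^2 = 2 uA/cm^2
        curve = fixture_curve("linear_voc_const_C", voc_slope=2e5, cap0=3e-9)
        ct = coupling_terms(0.02, -0.5, -60.0, curve)
        assert ct.I_drive == pytest.approx(2.0, rel=1e-9)
        # sign flips with the motion direction
        assert coupling_terms(0.02, 0.5, -60.0, curve).I_drive == pytest.approx(
            -2.0, rel=1e-9
        )

    def test_overlarge_capacitance_rejected(self):
        curve = fixture_curve("constant", cap0=2e-6)  # 1.33 uF/cm^2 > C_m
        with pytest.raises(ModelValidityError):
            coupling_terms(0.02, 0.1, -60.0, curve, C_m=1.0)


class TestReduction:
    def test_single_step_v0_equals_plain(self, short_axon, membrane, flat_curve):
        state = resting_state(short_axon, membrane)
        prof = MotionProfile(v=0.0)
        s_coupled = step_coupled(state, prof, flat_curve, membrane, short_axon)
        s_plain = step_plain(state, StimulusProtocol(), membrane, short_axon)
        np.testing.assert_array_equal(s_coupled.V, s_plain.V)

    def test_full_run_v0_bit_identical(self, membrane, flat_curve):
        cfg = AxonConfig(t_end=40.0)
        r_plain = run_plain(cfg, p=membrane)
        r_coupled = run_coupled(cfg, MotionProfile(v=0.0), flat_curve, p=membrane)
        np.testing.assert_array_equal(r_coupled.V_trace, r_plain.V_trace)

    def test_constant_capacitance_rescales_membrane(self, membrane):
        """Zero V_oc, constant C: the coupled run equals a plain run with
        C_m replaced by C_m - C, bit for bit."""
        curve = fixture_curve("zero_voc_const_C", cap0=3e-9)
        cfg = AxonConfig(t_end=20.0)
        stim = StimulusProtocol(amplitude=8.0, t_on=1.0, t_off=15.0)
        ct = coupling_terms(0.02, 0.1, -60.0, curve)
        assert ct.C_x > 0
        r_coupled = run_coupled(
            cfg, MotionProfile(v=0.1), curve, stim=stim, p=membrane
        )
        rescaled = dataclasses.replace(membrane, C_m=membrane.C_m - ct.C_x)
        r_plain = run_plain(cfg, stim, rescaled)
        np.testing.assert_array_equal(r_coupled.V_trace, r_plain.V_trace)


class TestCoupledRuns:
    def test_fast_motion_excites_resting_neuron(self, membrane, flat_curve, axon):
        res = run_coupled(axon, MotionProfile(v=0.5), flat_curve, p=membrane)
        t, v = res.compartment_trace()
        assert len(detect_spikes(t, v)) >= 1

    def test_slow_motion_subthreshold_elevation(self, membrane, flat_curve, axon):
        res = run_coupled(axon, MotionProfile(v=0.025), flat_curve, p=membrane)
        t, v = res.compartment_trace()
        assert len(detect_spikes(t, v)) == 0
        late = t >= 100.0
        assert np.mean(v[late]) > v[0]  # elevated resting baseline

    def test_trajectory_logged(self, membrane, flat_curve):
        cfg = AxonConfig(t_end=10.0)
        res = run_coupled(cfg, MotionProfile(v=0.2), flat_curve, p=membrane)
        assert res.x_t is not None and len(res.x_t) == len(res.times)
        assert res.x_t[0] == pytest.approx(0.05)

    def test_curve_must_cover_motion_range(self, membrane):
        narrow = fixture_curve("paperlike", x_max=1e-4)  # 0.01 cm only
        cfg = AxonConfig(t_end=10.0)
        with pytest.raises(ValueError):
            run_coupled(cfg, MotionProfile(v=0.5), narrow, p=membrane)
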
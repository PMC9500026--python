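"""Electrolysis pump model: stoichiometry, membrane laws, closed form vs ODE."""

import numpy as np
import pytest

from optofluidics import pump

from conftest import random_small_mstar_system


class TestGasGeneration:
    def test_zero_current_generates_no_gas(self):
        assert pump.gas_generation_rate(0.0) == 0.0

    def test_one_milliamp_rate(self):
        # 3 * 1e-3 / (4 * 96485), hand arithmetic
        assert pump.gas_generation_rate(1e-3) == pytest.approx(7.77323e-9, rel=1e-5)

    def test_linearity(self):
        assert pump.gas_generation_rate(2e-4) == pytest.approx(
            2 * pump.gas_generation_rate(1e-4)
        )

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            pump.gas_generation_rate(-1e-4)


class TestEffectiveCurrent:
    @pytest.mark.parametrize(
        "duty,peak,expected",
        [(0.1, 1e-3, 1e-4), (0.0, 1e-3, 0.0), (1.0, 5e-4, 5e-4)],
    )
    def test_duty_cycle_average(self, duty, peak, expected):
        drive = pump.DriveWaveform(duty_cycle=duty, peak_current=peak)
        assert pump.effective_current(drive) == pytest.approx(expected)

    def test_pwm_charge_bookkeeping(self):
        drive = pump.DriveWaveform(period=0.25, duty_cycle=0.1, peak_current=1e-3,
                                   duration=10.0)
        # after N full periods the charge equals N * duty * period * peak
        assert drive.charge(2.5) == pytest.approx(10 * 0.1 * 0.25 * 1e-3)
        # mid on-phase
        assert drive.charge(0.01) == pytest.approx(1e-3 * 0.01)


class TestMembraneLaws:
    def test_undeformed_membrane_zero_pressure(self):
        assert pump.membrane_pressure(0.0, pump.MembraneSpec()) == 0.0

    def test_linear_law_at_full_reservoir(self):
        # 64 E h^3 V / (3 pi R0^6) at E=4 MPa, h=150 um, R0=1.2 mm, V=500 nL
        f = pump.membrane_pressure(500e-12, pump.MembraneSpec())
        assert f == pytest.approx(1.53506e4, rel=1e-5)

    @pytest.mark.parametrize("law", ["linear", "spherical_cap"])
    def test_strictly_increasing(self, law):
        mem = pump.MembraneSpec(law=law)
        vols = np.linspace(0, 500e-12, 20)
        ps = [mem.pressure(v) for v in vols]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_tabulated_knot_identity(self):
        table = ((1e-10, 1e3), (2e-10, 3e3), (4e-10, 9e3))
        mem = pump.MembraneSpec(law="tabulated", table=table)
        for v, p in table:
            assert mem.pressure(v) == pytest.approx(p)

    def test_tabulated_must_be_monotone(self):
        with pytest.raises(ValueError):
            pump.MembraneSpec(law="tabulated", table=((1e-10, 2e3), (2e-10, 1e3)))

    def test_travel_limit_saturation_error(self):
        mem = pump.MembraneSpec(max_volume=100e-12)
        with pytest.raises(pump.MembraneTravelError):
            mem.pressure(200e-12)


class TestNondimensionalGroups:
    def test_normalized_ambient_pressure(self, default_system):
        groups = pump.nondimensionalize(default_system, 1e-3)
        assert groups.p0_star == pytest.approx(0.20260, rel=1e-4)

    def test_normalized_volume_identity(self):
        mem = pump.MembraneSpec()
        system = pump.PumpSystem(
            membrane=mem, initial_gas_volume_V0=mem.radius_R0**3
        )
        assert pump.nondimensionalize(system, 1e-4).v0_star == pytest.approx(1.0)

    def test_zero_current_rejected(self, default_system):
        with pytest.raises(ValueError):
            pump.nondimensionalize(default_system, 0.0)

    def test_linear_law_group(self, default_system):
        # G(V*) for the linear law is (64 h^2 / 3 pi R0^2) V*
        g = pump.nondimensionalize(default_system, 1e-4)
        v_star = 0.1
        assert g.G(v_star) == pytest.approx(g.g_linear * v_star, rel=1e-9)


class TestClosedForm:
    def test_initial_condition(self, default_system):
        groups = pump.nondimensionalize(default_system, 1e-4)
        assert pump.solve_volume_closed_form(0.0, groups) == 0.0
        assert pump.flow_rate_closed_form(0.0, groups) == pytest.approx(0.0, abs=1e-12)

    def test_volume_monotone(self, big_reservoir_system):
        groups = pump.nondimensionalize(big_reservoir_system, 1e-4)
        t_star = np.linspace(0, 0.05, 40)
        v = pump.solve_volume_closed_form(t_star, groups)
        assert np.all(np.diff(v) >= -1e-12)

    def test_flow_nonnegative(self, big_reservoir_system):
        groups = pump.nondimensionalize(big_reservoir_system, 1e-4)
        q = pump.flow_rate_closed_form(np.linspace(0, 0.05, 40), groups)
        assert np.all(np.asarray(q) >= -1e-12)

    def test_flow_is_derivative_of_volume(self, big_reservoir_system):
        groups = pump.nondimensionalize(big_reservoir_system, 1e-4)
        ts = np.linspace(1e-3, 0.04, 15)
        h = 1e-6
        for t in ts:
            num = (
                pump.solve_volume_closed_form(t + h, groups)
                - pump.solve_volume_closed_form(t - h, groups)
            ) / (2 * h)
            assert pump.flow_rate_closed_form(t, groups) == pytest.approx(
                num, rel=1e-4
            )

    def test_strict_mode_raises_beyond_reservoir(self, default_system):
        groups = pump.nondimensionalize(default_system, 1e-4)
        with pytest.raises(pump.ClosedFormRangeError):
            pump._v_sol_star(10.0, groups, clamp=False)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_ode_in_validity_regime(self, trial):
        """Closed form and dimensional ODE agree within 1% on randomized
        parameter sets with small normalized viscous resistance M*."""
        rng = np.random.default_rng(1000 + trial)
        system, current = random_small_mstar_system(rng)
        groups = pump.nondimensionalize(system, current)
        assert groups.m_star < 1e-3
        duration = min(0.1 * groups.time_scale, 2000.0)
        drive = pump.DriveWaveform(
            period=duration, duty_cycle=1.0, peak_current=current, duration=duration
        )
        prof = pump.integrate_pump_ode(system, drive, dt=duration / 4000)
        ts = prof.time[::10] / groups.time_scale
        q_cf = np.array(
            [pump.flow_rate_closed_form(t, groups) for t in ts]
        ) * system.membrane.radius_R0**3 / groups.time_scale
        err = abs(prof.peak_flow_rate - q_cf.max()) / prof.peak_flow_rate
        assert err < 0.01

    def test_error_shrinks_with_mstar(self):
        """The closed form is a leading-order solution in M*: halving the
        viscosity (hence M*) must shrink the ODE disagreement."""
        errs = []
        for mu in (0.89e-3, 0.89e-4):
            system = pump.PumpSystem(
                fluid=pump.FluidProperties(viscosity=mu), reservoir_volume=5e-9
            )
            drive = pump.DriveWaveform(period=30.0, duty_cycle=1.0,
                                       peak_current=1e-3, duration=30.0)
            prof = pump.integrate_pump_ode(system, drive, dt=0.01)
            groups = pump.nondimensionalize(system, 1e-3)
            ts = prof.time[::20] / groups.time_scale
            q_cf = np.array(
                [pump.flow_rate_closed_form(t, groups) for t in ts]
            ) * system.membrane.radius_R0**3 / groups.time_scale
            errs.append(abs(prof.peak_flow_rate - q_cf.max()) / prof.peak_flow_rate)
        assert errs[1] < 0.3 * errs[0]


class TestOdeIntegration:
    def test_zero_current_is_quiescent(self, default_system):
        drive = pump.DriveWaveform(duty_cycle=0.0, peak_current=0.0, duration=2.0)
        prof = pump.integrate_pump_ode(default_system, drive)
        assert np.allclose(prof.flow_rate, 0.0)
        assert np.allclose(prof.pressure, default_system.ambient_pressure_P0)

    def test_gas_mole_conservation(self, default_system):
        drive = pump.DriveWaveform(period=0.25, duty_cycle=0.1,
                                   peak_current=1e-3, duration=20.0)
        prof = pump.integrate_pump_ode(default_system, drive)
        expected = default_system.initial_moles + 3.0 * np.array(
            [drive.charge(t) for t in prof.time]
        ) / (4.0 * default_system.faraday_F)
        rel = np.abs(prof.moles(default_system) - expected) / expected
        assert rel.max() < 1e-6

    def test_delivered_monotone_and_bounded(self, default_system):
        drive = pump.DriveWaveform(period=0.25, duty_cycle=0.5,
                                   peak_current=1e-3, duration=60.0)
        prof = pump.integrate_pump_ode(default_system, drive)
        assert np.all(np.diff(prof.delivered_volume) >= -1e-18)
        assert prof.total_delivered <= default_system.reservoir_volume * (1 + 1e-9)
        # strong drive empties the ~500 nL reservoir
        assert prof.total_delivered == pytest.approx(
            default_system.reservoir_volume, rel=1e-3
        )

    def test_dt_must_resolve_pwm(self, default_system):
        drive = pump.DriveWaveform(period=0.25, duty_cycle=0.1, duration=1.0)
        with pytest.raises(ValueError):
            pump.integrate_pump_ode(default_system, drive, dt=0.1)

    def test_pressure_volume_product_grows_linearly(self, default_system):
        """Isothermal ideal-gas bookkeeping: P (V + V0) rises at ndot R T
        under constant current."""
        i = 1e-4
        drive = pump.DriveWaveform(period=5.0, duty_cycle=1.0,
                                   peak_current=i, duration=5.0)
        prof = pump.integrate_pump_ode(default_system, drive, dt=0.005)
        pv = prof.pressure * (prof.gas_volume + default_system.initial_gas_volume_V0)
        slope = np.polyfit(prof.time, pv, 1)[0]
        expected = pump.gas_generation_rate(i) * (
            default_system.gas_constant_R * default_system.temperature_T
        )
        assert slope == pytest.approx(expected, rel=1e-6)

    def test_resistance_vanishes_continuously(self):
        """Peak flow converges as viscosity tends to zero."""
        peaks = []
        for mu in (3e-5, 1e-5):
            system = pump.PumpSystem(fluid=pump.FluidProperties(viscosity=mu))
            drive = pump.DriveWaveform(period=5.0, duty_cycle=1.0,
                                       peak_current=1e-4, duration=5.0)
            prof = pump.integrate_pump_ode(system, drive, dt=2e-4)
            peaks.append(prof.peak_flow_rate)
        assert peaks[1] == pytest.approx(peaks[0], rel=0.02)


class TestPeakFlowCurve:
    def test_monotone_in_current(self, default_system):
        currents = [1e-4, 2.5e-4, 5e-4, 1e-3]
        peaks = pump.max_flow_rate_vs_current(default_system, currents)
        assert np.all(np.diff(peaks) > 0)

    def test_empty_current_list_rejected(self, default_system):
        with pytest.raises(ValueError):
            pump.max_flow_rate_vs_current(default_system, [])

    def test_grid_refinement_stability(self, default_system):
        drive_dur = 30.0
        coarse = pump.max_flow_rate_vs_current(
            default_system, [2.5e-4, 1e-3], duration=drive_dur, dt=drive_dur / 3000
        )
        fine = pump.max_flow_rate_vs_current(
            default_system, [2.5e-4, 1e-3], duration=drive_dur, dt=drive_dur / 6000
        )
        assert np.all(np.abs(fine - coarse) / fine < 0.005)


class TestProtocols:
    def test_empty_schedule(self, default_system):
        result = pump.simulate_protocol(default_system, pump.ProtocolSchedule(()))
        assert result.profile.time.size == 0
        assert result.phase_delivered == []

    def test_overlapping_same_channel_phases_rejected(self):
        with pytest.raises(ValueError):
            pump.ProtocolSchedule(
                (
                    pump.Phase("pump", duration=10.0, start=0.0),
                    pump.Phase("pump", duration=10.0, start=5.0),
                )
            )

    def test_logic1_delivers_everything_in_pump_phase(self, default_system):
        result = pump.simulate_protocol(default_system, pump.logic1_schedule())
        total = result.profile.total_delivered
        assert result.phase_delivered[0] == pytest.approx(total, rel=1e-6)
        assert result.phase_delivered[1] == pytest.approx(0.0, abs=total * 1e-6)
        assert len(result.led_epochs) == 1

    def test_logic2_conserves_total_delivery(self, big_reservoir_system):
        """Equal total pump-on time at the same drive yields the same final
        delivered volume once pressure has relaxed (reservoir sized so no
        phase is truncated; every pump phase then delivers an increment)."""
        r1 = pump.simulate_protocol(
            big_reservoir_system, pump.logic1_schedule(peak_current=1e-4),
            settle_time=120.0,
        )
        r2 = pump.simulate_protocol(
            big_reservoir_system, pump.logic2_schedule(peak_current=1e-4),
            settle_time=120.0,
        )
        assert r2.profile.total_delivered == pytest.approx(
            r1.profile.total_delivered, rel=1e-3
        )
        assert len(r2.phase_delivered) == 16
        assert sum(1 for d in r2.phase_delivered[::2] if d > 0) == 8
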
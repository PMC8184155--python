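"""Unit tests of the conductance-based LIF primitives.

The analytic oracles here (closed-form leak relaxation, driven-LIF
interspike interval, fine-step reference integration of the NMDA kinetics,
shot-noise steady state) are independent of the integrator they check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ringdpx.lif_core import (PopulationState, SpikeRecord, ampa_current,
                              mg_block_factor, nmda_current, poisson_drive,
                              step_population, synaptic_currents,
                              update_first_order_kinetics,
                              update_nmda_kinetics)
from ringdpx.params import (ReceptorParams, default_interneuron_cell,
                            default_pyramidal_cell,
                            default_pyramidal_receptors)


class TestMgBlock:
    def test_no_magnesium_removes_block(self):
        for vm in (-80.0, -60.0, 0.0, 30.0):
            assert mg_block_factor(vm, 0.0) == 1.0

    def test_hand_evaluated_value_at_zero_mv(self):
        # 1 / (1 + 1/3.57)
        assert mg_block_factor(0.0, 1.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57),
                                                          rel=1e-12)

    @given(st.floats(-120.0, 20.0), st.floats(-120.0, 20.0))
    def test_strictly_increasing_in_voltage(self, v1, v2):
        if abs(v1 - v2) < 1e-6:
            return
        lo, hi = sorted((v1, v2))
        assert mg_block_factor(lo, 1.0) < mg_block_factor(hi, 1.0)

    @given(st.floats(-200.0, 50.0), st.floats(0.0, 10.0))
    def test_bounded_in_unit_interval(self, vm, mg):
        f = mg_block_factor(vm, mg)
        assert 0.0 < f <= 1.0


class TestSynapticCurrents:
    def _state(self, vm, s_nmda=0.0, s_gaba=0.0, s_noise=0.0, s_aff=0.0):
        z = lambda v: np.array([float(v)])
        return PopulationState(Vm=z(vm), refrac_until=z(-np.inf),
                               x_nmda=z(0.0), s_nmda=z(s_nmda),
                               s_gaba=z(s_gaba), s_ampa_noise=z(s_noise),
                               s_ampa_aff=z(s_aff))

    def test_zero_gating_gives_zero_currents(self):
        params = default_pyramidal_receptors()
        currents = synaptic_currents(self._state(-60.0), params)
        for I in currents:
            assert np.all(I == 0.0)

    def test_nmda_current_vanishes_at_reversal(self):
        params = default_pyramidal_receptors()
        I_nmda, *_ = synaptic_currents(self._state(params.V_E, s_nmda=0.7),
                                       params)
        assert np.all(I_nmda == 0.0)

    def test_single_source_formula(self):
        # I = g * s * (Vm - V_E) * mg_block
        I = nmda_current(-60.0, 0.5, 0.37, V_E=0.0, Mg=1.0)
        expected = 0.37 * 0.5 * (-60.0) * mg_block_factor(-60.0, 1.0)
        assert I == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_detected(self):
        params = default_pyramidal_receptors()
        state = self._state(-60.0, s_nmda=0.5)
        with pytest.raises(ValueError):
            synaptic_currents(state, params, W_nmda=np.ones((3, 1)) / 3)


class TestFirstOrderKinetics:
    def test_pure_exponential_decay(self):
        s = 0.8
        tau, dt = 10.0, 0.05
        for k in range(200):
            s = update_first_order_kinetics(s, 0.0, dt, tau)
        assert s == pytest.approx(0.8 * math.exp(-10.0 / tau), rel=1e-12)

    def test_spike_jumps_by_connection_weight(self):
        s0, w, dt, tau = 0.2, 0.004, 0.05, 2.0
        s1 = update_first_order_kinetics(s0, w, dt, tau)
        assert s1 == pytest.approx((s0 + w) * math.exp(-dt / tau), rel=1e-12)

    def test_poisson_drive_reaches_shot_noise_mean(self):
        # steady-state mean of jump-decay shot noise is r * w * tau
        rng = np.random.default_rng(7)
        rate_khz, w, tau, dt = 1.8, 0.001, 2.0, 0.05
        s, total, count = 0.0, 0.0, 0
        n_steps = int(10_000 / dt)
        for k in range(n_steps):
            s = update_first_order_kinetics(s, w * rng.poisson(rate_khz * dt),
                                            dt, tau)
            if k > 2000:
                total += s
                count += 1
        expected = rate_khz * w * tau
        assert total / count == pytest.approx(expected, rel=0.05)


class TestNmdaKinetics:
    def test_origin_is_fixed_point(self):
        x, s = update_nmda_kinetics(np.zeros(3), np.zeros(3), 0.0, 0.05)
        assert np.all(x == 0.0) and np.all(s == 0.0)

    def test_open_fraction_saturates_below_one(self):
        x, s = np.zeros(1), np.zeros(1)
        rng = np.random.default_rng(0)
        for _ in range(20_000):  # 1 s of 100 Hz driving
            spikes = rng.poisson(0.1 * 0.05)
            x, s = update_nmda_kinetics(x, s, spikes, 0.05)
            assert 0.0 <= s[0] <= 1.0

    def test_single_spike_matches_fine_step_reference(self):
        dt = 0.05
        x, s = update_nmda_kinetics(np.zeros(1), np.zeros(1), 1.0, dt)
        traj = [(x[0], s[0])]
        for _ in range(int(200.0 / dt) - 1):
            x, s = update_nmda_kinetics(x, s, 0.0, dt)
            traj.append((x[0], s[0]))

        # reference: same ODEs at dt = 0.001 ms
        dt_ref = 0.001
        xr, sr = 1.0, 0.0
        ref = {}
        for k in range(1, int(200.0 / dt_ref) + 1):
            k1x = -xr / 2.0
            k1s = xr * (1.0 - sr) - sr / 80.0
            x1, s1 = xr + dt_ref * k1x, sr + dt_ref * k1s
            k2x = -x1 / 2.0
            k2s = x1 * (1.0 - s1) - s1 / 80.0
            xr += 0.5 * dt_ref * (k1x + k2x)
            sr += 0.5 * dt_ref * (k1s + k2s)
            ref[round(k * dt_ref, 6)] = (xr, sr)

        for i in (100, 400, 1600, 3999):  # 5, 20, 80, 200 ms
            t = round((i + 1) * dt, 6)
            x_ref, s_ref = ref[t]
            # s (the quantity entering currents) agrees to 1e-4 relative;
            # x to 1e-4 absolute on the unit per-spike increment scale
            assert traj[i][0] == pytest.approx(x_ref, abs=1e-4)
            assert traj[i][1] == pytest.approx(s_ref, rel=1e-4)

    def test_x_decays_exponentially_between_spikes(self):
        dt = 0.05
        x, s = update_nmda_kinetics(np.zeros(1), np.zeros(1), 1.0, dt)
        for _ in range(int(10.0 / dt) - 1):
            x, s = update_nmda_kinetics(x, s, 0.0, dt)
        # RK2 truncation on the pure decay accumulates ~(dt/tau)^3/6 per step
        assert x[0] == pytest.approx(math.exp(-10.0 / 2.0), rel=1e-3)


class TestStepPopulation:
    def test_leak_only_matches_closed_form(self):
        # V(t) = V_L + (V0 - V_L) exp(-t / (Cm/gL))
        for cell in (default_pyramidal_cell(), default_interneuron_cell()):
            vm = np.array([-50.0 + 1e-9])  # just below threshold is fine
            vm[0] = -55.0
            refrac = np.array([-np.inf])
            dt, t = 0.05, 0.0
            zero = lambda v, stage: 0.0
            for k in range(int(100.0 / dt)):
                vm, refrac, spiked, _ = step_population(vm, refrac, t, dt,
                                                        cell, zero)
                t += dt
                assert not spiked.any()
            tau = cell.Cm / cell.gL
            expected = cell.V_L + (-55.0 - cell.V_L) * math.exp(-100.0 / tau)
            assert abs(vm[0] - expected) / abs(expected) < 1e-5

    def test_refractory_neuron_ignores_input(self):
        cell = default_pyramidal_cell()
        vm = np.array([cell.V_rest])
        refrac = np.array([10.0])  # refractory until t = 10 ms
        huge = lambda v, stage: -100.0  # strongly depolarizing
        vm, refrac, spiked, _ = step_population(vm, refrac, 0.0, 0.05, cell,
                                                huge)
        assert not spiked.any()
        assert vm[0] == cell.V_rest

    def test_driven_isi_matches_analytic(self):
        # constant suprathreshold current: ISI = tau_ref + tau ln((Vinf-Vr)/(Vinf-Vth))
        cell = default_pyramidal_cell()
        I0 = 0.8  # nA injected (suprathreshold: > gL (V_th - V_L) = 0.5)
        vm = np.array([cell.V_rest])
        refrac = np.array([-np.inf])
        inject = lambda v, stage: -I0
        dt, t = 0.05, 0.0
        spike_times = []
        while t < 400.0:
            vm, refrac, spiked, t_spk = step_population(vm, refrac, t, dt,
                                                        cell, inject)
            if spiked.any():
                spike_times.append(t_spk[0])
            t += dt
        v_inf = cell.V_L + I0 / cell.gL
        tau = cell.Cm / cell.gL
        isi_exact = cell.tau_ref + tau * math.log(
            (v_inf - cell.V_rest) / (v_inf - cell.V_th))
        isis = np.diff(spike_times)
        assert isis.size > 10
        assert np.mean(isis) == pytest.approx(isi_exact, rel=0.01)

    def test_halving_dt_converges(self):
        # < 1e-3 mV RMS difference over a 1-s deterministic trajectory
        cell = default_pyramidal_cell()
        inject = lambda v, stage: -0.2  # subthreshold depolarization

        def trajectory(dt):
            vm = np.array([cell.V_rest])
            refrac = np.array([-np.inf])
            t, out = 0.0, []
            for k in range(int(1000.0 / dt)):
                vm, refrac, _, _ = step_population(vm, refrac, t, dt, cell,
                                                   inject)
                t += dt
                if abs(round(t / 1.0) - t / 1.0) < 1e-9:  # every 1 ms
                    out.append(vm[0])
            return np.asarray(out)

        a, b = trajectory(0.05), trajectory(0.025)
        rms = np.sqrt(np.mean((a - b[:a.size]) ** 2))
        assert rms < 1e-3

    def test_no_spontaneous_spikes_without_drive(self):
        cell = default_pyramidal_cell()
        vm = np.full(16, cell.V_rest)
        refrac = np.full(16, -np.inf)
        zero = lambda v, stage: 0.0
        t = 0.0
        for _ in range(4000):
            vm, refrac, spiked, _ = step_population(vm, refrac, t, 0.05,
                                                    cell, zero)
            assert not spiked.any()
            t += 0.05


class TestPoissonDrive:
    def test_zero_rate_yields_no_events(self):
        rng = np.random.default_rng(0)
        counts = poisson_drive(np.zeros(50), 0.05, rng)
        assert np.all(counts == 0)

    def test_background_rate_recovered(self):
        # 1.8 kHz over 10 s across 100 neurons: mean within 1%
        rng = np.random.default_rng(42)
        total = 0
        n_steps = int(10_000 / 0.05)
        lam = np.full(100, 1.8)
        for _ in range(200):
            total += poisson_drive(lam, 0.05 * n_steps / 200, rng).sum()
        rate = total / 100 / 10.0 / 1000.0  # kHz
        assert rate == pytest.approx(1.8, rel=0.01)

    def test_identical_seeds_identical_streams(self):
        a = np.random.default_rng(123)
        b = np.random.default_rng(123)
        for _ in range(10):
            ca = poisson_drive(np.full(64, 1.8), 0.05, a)
            cb = poisson_drive(np.full(64, 1.8), 0.05, b)
            assert np.array_equal(ca, cb)


class TestSpikeRecord:
    def test_window_and_counts(self):
        rec = SpikeRecord([3, 1, 3], [5.0, 1.0, 2.0], n_neurons=4)
        assert np.array_equal(rec.time_ms, [1.0, 2.0, 5.0])
        w = rec.window(1.5, 5.0)
        assert len(w) == 1 and w.neuron[0] == 3
        assert np.array_equal(rec.counts(0.0, 10.0), [0, 1, 0, 2])

    def test_mean_rate(self):
        rec = SpikeRecord(np.zeros(10, int), np.linspace(0, 99, 10), 10)
        assert rec.mean_rate_hz(0.0, 100.0) == pytest.approx(10.0)
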
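"""HH channels, optional channels, and synaptic machinery."""

import math

import numpy as np
import pytest

from chloridesim.membrane_mechanisms import (
    HHParams, AdaptationParams, SynapsePopulation, hh_step, hh_rates,
    hh_steady_state, adaptation_currents, sample_synaptic_events,
    synaptic_currents, ampa_carrier_split, periodic_events,
    events_to_text, events_from_text)
from chloridesim.model_core import ghk_anion_reversal, nernst


class TestHH:
    def test_gates_converge_to_steady_state(self):
        v = -65.0
        gates = (0.5, 0.5, 0.5)
        for _ in range(5000):
            gates, _, _ = hh_step(v, gates, 0.05)
        m_inf, h_inf, n_inf = hh_steady_state(v)
        assert gates == pytest.approx((m_inf, h_inf, n_inf), abs=1e-6)

    def test_zero_density_zero_current(self):
        p = HHParams(gbar_Na=0.0, gbar_K=0.0)
        _, i_na, i_k = hh_step(-50.0, (0.5, 0.5, 0.5), 0.05, p)
        assert i_na == 0.0 and i_k == 0.0

    def test_spike_against_independent_ode_solver(self):
        """Euler-integrated HH patch vs scipy's adaptive solver on the
        same equations: both produce one spike with matching peak time."""
        from scipy.integrate import solve_ivp
        p = HHParams(gbar_Na=120.0, gbar_K=100.0)
        e_na, e_k, e_l, g_l = 40.0, -102.0, -80.0, 0.1
        i_inj = 10.0e-3  # mA/cm^2
        v0 = -80.0
        m0, h0, n0 = hh_steady_state(v0, p)

        def f(t, y):
            v, m, h, n = y
            am, bm, ah, bh, an, bn = hh_rates(v, p.V_T, p.V_S)
            i_na = p.gbar_Na * m ** 3 * h * (v - e_na)
            i_k = p.gbar_K * n ** 4 * (v - e_k)
            i_l = g_l * (v - e_l)
            dv = -(i_na + i_k + i_l) * 1e-3 * 1e3 + i_inj * 1e3
            return [dv, am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                    an * (1 - n) - bn * n]

        sol = solve_ivp(f, (0.0, 20.0), [v0, m0, h0, n0], max_step=0.01,
                        dense_output=True)
        t_ref = sol.t[np.argmax(sol.y[0])]
        v_ref_peak = sol.y[0].max()

        # our explicit path
        v, gates = v0, (m0, h0, n0)
        dt, peak, t_peak = 0.01, -100.0, 0.0
        for k in range(2000):
            gates, i_na, i_k = hh_step(v, gates, dt, p, e_na, e_k)
            i_l = g_l * (v - e_l) * 1e-3
            v += dt * (-(i_na + i_k + i_l) + i_inj) * 1e3
            if v > peak:
                peak, t_peak = v, k * dt
        assert v_ref_peak > 0 and peak > 0
        assert t_peak == pytest.approx(t_ref, abs=1.0)

    def test_instability_tolerated_by_clamping(self):
        gates, _, _ = hh_step(60.0, (0.999, 0.5, 0.5), 5.0)
        assert all(0.0 <= g <= 1.0 for g in gates)


class TestAdaptation:
    def test_zero_conductance_zero_current(self):
        gates = (0.1, 0.2, 0.3, 0.4)
        _, i_ahp, i_nap = adaptation_currents(-50.0, gates, 0.05)
        assert i_ahp == 0.0 and i_nap == 0.0

    def test_slow_gate_integrates_activation(self):
        p = AdaptationParams(gbar_AHP=1.0)
        gates = (0.0, 0.0, 0.0, 1.0)
        for _ in range(2000):          # 100 ms at 0 mV
            gates, _, _ = adaptation_currents(0.0, gates, 0.05, p)
        m, z = gates[0], gates[1]
        assert m > 0.9                 # fast gate essentially open
        assert 0.05 < z < 0.2          # z integrates on the 1-s scale


class TestPoissonEvents:
    POP = SynapsePopulation(0, "GABA_A", 100, 0.8)

    def test_zero_rate_empty(self):
        pop = SynapsePopulation(0, "GABA_A", 100, 0.0)
        t, g = sample_synaptic_events(pop, 0.0, 1e5, 1)
        assert t.size == 0

    def test_poisson_count(self):
        t, g = sample_synaptic_events(self.POP, 0.0, 100e3, 12345)
        expected = 100 * 0.8 * 100.0
        assert abs(t.size - expected) < 3 * math.sqrt(expected)

    def test_determinism(self):
        t1, g1 = sample_synaptic_events(self.POP, 0.0, 1e4, 7)
        t2, g2 = sample_synaptic_events(self.POP, 0.0, 1e4, 7)
        assert np.array_equal(t1, t2) and np.array_equal(g1, g2)

    def test_conductances_truncated_positive(self):
        pop = SynapsePopulation(0, "GABA_A", 200, 5.0, gmax_mean=0.1,
                                gmax_sd=1.0)
        _, g = sample_synaptic_events(pop, 0.0, 1e4, 3)
        assert np.all(g > 0)

    def test_events_text_round_trip(self, tmp_path):
        t, g = sample_synaptic_events(self.POP, 0.0, 1e3, 11)
        path = tmp_path / "events.csv"
        comps = np.zeros(t.size, dtype=int)
        kinds = ["GABA_A"] * t.size
        events_to_text(path, t, comps, kinds, g)
        t2, c2, k2, g2 = events_from_text(path)
        assert np.array_equal(t, t2) and np.array_equal(g, g2)

    def test_periodic_train(self):
        t, g = periodic_events(50.0, 0.0, 1000.0, 1.0)
        assert t.size == 50
        assert np.allclose(np.diff(t), 20.0)


class TestSynapticCurrents:
    E_CL = nernst(-1, 6.0, 120.0)
    E_HCO3 = nernst(-1, 15.0, 25.0)

    def test_reversal_of_composite_gaba_current(self):
        # the ohmic 4:1 split reverses at the conductance-weighted mean of
        # the two Nernst potentials, within ~2 mV of the GHK E_GABA
        e_rev = 0.8 * self.E_CL + 0.2 * self.E_HCO3
        i = synaptic_currents(e_rev, 1.0, 0.0, self.E_CL, self.E_HCO3)
        assert i[2] + i[3] == pytest.approx(0.0, abs=1e-12)
        assert i[2] > 0 and i[3] < 0   # opposite charge flow
        e_gaba = ghk_anion_reversal(6, 120, 15, 25, 4)
        assert abs(e_rev - e_gaba) < 2.0

    def test_conductance_decay_efold(self):
        g = 1.0
        for _ in range(600):           # 30 ms at dt = 0.05
            out = synaptic_currents(-70.0, g, 0.0, self.E_CL, self.E_HCO3,
                                    dt=0.05, tau_gaba=30.0)
            g = out[4]
        assert g == pytest.approx(1.0 / math.e, rel=1e-6)

    def test_collapsed_cl_gradient_gives_inward_current(self):
        # raise [Cl-]i until E_Cl = V: the remaining GABA current is the
        # inward HCO3- component
        v = -60.0
        i = synaptic_currents(v, 1.0, 0.0, v, self.E_HCO3)
        assert i[2] == 0.0
        assert i[3] < 0.0              # net inward, carried by HCO3-

    def test_ampa_split_reverses_at_zero(self):
        e_na, e_k = nernst(1, 10, 45), nernst(1, 140, 3)
        f = ampa_carrier_split(e_na, e_k)
        i = synaptic_currents(0.0, 0.0, 1.0, self.E_CL, self.E_HCO3,
                              e_na=e_na, e_k=e_k, ampa_frac_na=f)
        assert i[0] + i[1] == pytest.approx(0.0, abs=1e-12)
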
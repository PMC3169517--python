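"""Integration engine: stepping, conservation, clamps, determinism."""

import numpy as np
import pytest

from chloridesim.constants import (FARADAY, SPECIES, VALENCE, ICL, IK, INA,
                                   IHCO3)
from chloridesim.engine import (SimConfig, Simulation, run,
                                relax_to_rest, measure_steady_state,
                                nominal_state)
from chloridesim.model_core import build_cell, GeometryConfig


class TestFixedPointAndDeterminism:
    def test_all_mechanisms_disabled_is_fixed_point(self, small_cell):
        cfg = SimConfig(duration=5.0, record_interval=0.05,
                        mechanisms_enabled=False, ecs_diffusion=False)
        sim = Simulation(cfg, small_cell)
        v0 = sim.state.V.copy()
        ci0 = sim.state.Ci.copy()
        rec = sim.run()
        assert np.allclose(rec.final_state.V, v0, atol=1e-9)
        assert np.allclose(rec.final_state.Ci, ci0, rtol=1e-9)

    def test_bit_identical_reruns(self, small_cell):
        cfg = SimConfig(duration=500.0, seed=42, f_inh=2.0, f_exc=0.5)
        r1 = run(cfg, small_cell)
        r2 = run(cfg, small_cell)
        assert np.array_equal(r1.V, r2.V)
        assert np.array_equal(r1.Ci_out, r2.Ci_out)
        assert np.array_equal(r1.Co, r2.Co)

    def test_different_seeds_differ(self, small_cell):
        r1 = run(SimConfig(duration=500.0, seed=1, f_inh=2.0), small_cell)
        r2 = run(SimConfig(duration=500.0, seed=2, f_inh=2.0), small_cell)
        assert not np.array_equal(r1.V, r2.V)

    def test_zero_duration_returns_initial_state(self, small_cell):
        rec = run(SimConfig(duration=0.0), small_cell)
        assert rec.t.size == 1
        init = nominal_state(small_cell, SimConfig())
        assert np.allclose(rec.V[0], init.V)
        assert np.allclose(rec.Ci_out[0], init.Ci[:, :, 0])


class TestConservation:
    def test_charge_books_match_membrane_potential(self, soma_only_cell):
        """For an isolated compartment, the ionic charge moved across the
        membrane must equal the capacitive charge C*dV (species-carrying
        mechanisms only; chemistry is charge-neutral per reaction)."""
        from chloridesim.electrodiffusion import DiffusionParams
        cfg = SimConfig(duration=50.0, record_interval=0.05,
                        ecs_diffusion=False, nah_scale=0.0,
                        diffusion=DiffusionParams(tau_FH=1e15),
                        init="nominal")
        sim = Simulation(cfg, soma_only_cell)
        ci0 = sim.state.Ci.copy()
        v0 = sim.state.V.copy()
        rec = sim.run()
        st = rec.final_state
        vol_ann = sim.geom.vol_ann
        dq = 0.0
        for x in range(8):
            d_moles = ((st.Ci[x, 0] - ci0[x, 0]) * vol_ann[0]).sum() * 1e-6
            dq += VALENCE[x] * FARADAY * d_moles        # coulombs gained
        area = soma_only_cell.area_cm2[0]
        c_m = cfg.constants.C_m * 1e-6 * area           # farads
        dq_cap = c_m * (st.V[0] - v0[0]) * 1e-3         # coulombs
        assert dq == pytest.approx(dq_cap, rel=1e-3, abs=1e-16)

    def test_membrane_efflux_lands_in_shell(self, soma_only_cell):
        """Moles leaving the cytosol appear in the FH shell exactly when
        bath relaxation is switched off."""
        from chloridesim.electrodiffusion import DiffusionParams
        cfg = SimConfig(duration=200.0, ecs_diffusion=False,
                        diffusion=DiffusionParams(tau_FH=1e15))
        sim = Simulation(cfg, soma_only_cell)
        ci0 = sim.state.Ci.copy()
        co0 = sim.state.Co.copy()
        rec = sim.run()
        st = rec.final_state
        vol_ann = sim.geom.vol_ann
        shell = sim.geom.shell_vol
        for x in (ICL, IK, INA):
            lost = ((ci0[x, 0] - st.Ci[x, 0]) * vol_ann[0]).sum()
            gained = (st.Co[x, 0] - co0[x, 0]) * shell[0]
            # residual set by the (huge-tau) bath term, not by the books
            assert gained == pytest.approx(lost, rel=1e-6, abs=1e-20)

    def test_no_negative_concentrations_under_load(self, small_cell):
        dend = small_cell.dendritic_ids()[-1]
        cfg = SimConfig(duration=2000.0, f_inh=5.0, f_exc=1.25, seed=0,
                        gaba_windows=[(int(dend), 5.0, 0.0, 2000.0)])
        rec = run(cfg, small_cell)
        assert rec.Ci_out.min() > 0.0


class TestClampsAndStimuli:
    def test_clamped_species_exact(self, small_cell):
        cfg = SimConfig(duration=500.0, f_inh=2.0, f_exc=0.5, seed=0,
                        clamp_species=("Cl", "HCO3"))
        sim = Simulation(cfg, small_cell)
        ci0 = sim.state.Ci.copy()
        rec = sim.run()
        assert np.array_equal(rec.final_state.Ci[ICL], ci0[ICL])
        assert np.array_equal(rec.final_state.Ci[IHCO3], ci0[IHCO3])
        assert not np.array_equal(rec.final_state.Ci[IK], ci0[IK])

    def test_shell_potassium_clamp(self, small_cell):
        cfg = SimConfig(duration=300.0, f_inh=2.0, seed=0,
                        clamp_shell={"K": 10.0})
        rec = run(cfg, small_cell)
        assert np.allclose(rec.Co[:, IK, :], 10.0)

    def test_voltage_clamp_holds(self, small_cell):
        cfg = SimConfig(duration=200.0, voltage_clamp=(0, -40.0))
        rec = run(cfg, small_cell)
        assert rec.V[:, 0] == pytest.approx(-40.0, abs=1e-3)

    def test_clamped_soma_cl_accumulation_scales_with_driving_force(
            self, small_cell):
        """Under voltage clamp with an open GABA conductance, the initial
        Cl- accumulation rate is proportional to V_clamp - E_Cl."""
        rates = {}
        for v in (-60.0, -40.0):
            cfg = SimConfig(duration=100.0, record_interval=1.0,
                            voltage_clamp=(0, v), kcc2_scale=0.0,
                            drift=False,
                            gaba_windows=[(0, 10.0, 0.0, 100.0)])
            rec = run(cfg, small_cell)
            cl = rec.Ci_out[:, ICL, 0]
            rates[v] = (cl[19] - cl[0]) / (rec.t[19] - rec.t[0])
        e_cl0 = 26.712 * np.log(6.0 / 120.0)
        expected = (-40.0 - e_cl0) / (-60.0 - e_cl0)
        assert rates[-40.0] / rates[-60.0] == pytest.approx(expected,
                                                            rel=0.05)


class TestSteadyStateMeasure:
    def _fake_record(self, t, series):
        class R:
            pass
        r = R()
        r.t = t
        return r

    def test_constant_and_sine(self, small_cell):
        rec = run(SimConfig(duration=100.0, record_interval=1.0),
                  small_cell)
        t = rec.t
        const = np.full(t.size, 3.14)
        m, sd = measure_steady_state(rec, const, 50.0)
        assert m == pytest.approx(3.14) and sd == pytest.approx(0.0)
        sine = 2.0 + np.sin(2 * np.pi * t / 10.0)
        m, _ = measure_steady_state(rec, sine, 50.0)
        assert m == pytest.approx(2.0, abs=0.05)
        with pytest.raises(ValueError):
            measure_steady_state(rec, sine, 1e6)


class TestRestingState:
    def test_resting_drift_below_one_percent_over_10s(self, default_cell):
        """From the relaxed no-input resting state, every concentration
        drifts < 1% and V < 1 mV over 10 simulated seconds."""
        rest = relax_to_rest(default_cell)
        cfg = SimConfig(duration=10000.0, record_interval=100.0, init=rest)
        rec = run(cfg, default_cell)
        st = rec.final_state
        for x, name in enumerate(SPECIES):
            rel = np.abs(st.Ci[x] - rest.Ci[x]) / rest.Ci[x]
            assert rel.max() < 0.01, f"{name} drifted {rel.max():.2%}"
        assert np.abs(st.V - rest.V).max() < 1.0

    def test_dt_halving_converges(self, small_cell):
        finals = {}
        for dt in (0.05, 0.025):
            cfg = SimConfig(duration=1000.0, dt=dt, record_interval=10.0,
                            gaba_windows=[(0, 2.0, 0.0, 1000.0)])
            rec = run(cfg, small_cell)
            finals[dt] = rec.Ci_out[-1, ICL, 0]
        assert abs(finals[0.025] - finals[0.05]) / finals[0.05] < 0.005


class TestKCC2Monotonicity:
    def test_more_kcc2_means_less_steady_chloride(self, small_cell):
        """Under a fixed held-open GABA load, raising the KCC2 activity
        scale monotonically lowers the steady [Cl-]i."""
        dend = int(small_cell.dendritic_ids()[-1])
        finals = []
        for scale in (0.33, 1.0, 3.0):
            cfg = SimConfig(duration=6000.0, record_interval=50.0,
                            kcc2_scale=scale,
                            gaba_windows=[(dend, 2.0, 0.0, 6000.0)])
            rec = run(cfg, small_cell)
            finals.append(rec.Ci_out[-1, ICL, dend])
        assert finals[0] > finals[1] > finals[2]
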
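"""Direction-of-effect protocol tests at reduced durations.

These run the shipped protocols at scaled-down problem sizes and assert
the qualitative behavior of the full experiments: standing gradients
need both noise and extrusion, distal IPSC trains invert without KCC2,
bicarbonate flux is what lets the GABA current invert, extracellular K+
tracks the Cl- load through KCC2, and the optional spike-modulating
channels move the firing rate in opposite directions.
"""

import numpy as np
import pandas as pd
import pytest

from chloridesim import protocols as P
from chloridesim.engine import SimConfig, run
from chloridesim.model_core import build_cell, GeometryConfig


def slope_vs_distance(df):
    fit = np.polyfit(df.distance_um, df.cl_mM, 1)
    return fit[0]


class TestSomatodendriticGradient:
    def test_gradient_requires_noise(self):
        """A standing somato-dendritic [Cl-]i gradient needs ongoing
        synaptic load: with KCC2 but no noise the profile stays flat.
        (The converse no-extrusion arm reaches its flat *elevated*
        profile only at equilibrium, beyond scaled durations; the
        protocol still produces it for inspection.)"""
        df = P.protocol_somatodendritic_gradient(duration_ms=8000.0)
        slopes = {}
        for noise in (True, False):
            for kcc2 in (True, False):
                sel = df[(df.noise == noise) & (df.kcc2 == kcc2)]
                slopes[(noise, kcc2)] = slope_vs_distance(sel)
        assert slopes[(True, True)] > 0
        assert slopes[(True, True)] > 2.0 * abs(slopes[(False, True)])
        # without extrusion the cell accumulates Cl- everywhere
        noisy = df[df.noise == True]
        assert noisy[~noisy.kcc2].cl_mM.mean() > noisy[noisy.kcc2].cl_mM.mean()


class TestIPSCTrains:
    @pytest.fixture(scope="class")
    def trains(self):
        return P.protocol_ipsc_train(sites_um=(0.0, 240.0),
                                     kcc2_scales=(1.0, 0.0),
                                     duration_ms=5000.0)

    def test_distal_accumulation_largest_without_kcc2(self, trains):
        """Repeated 40-Hz trains load the distal dendrite with Cl-;
        removing extrusion at t=0 makes the collapse larger, and the
        synaptic current drifts inward (less outward) as E_GABA rises."""
        def row(site, kc):
            return trains[(trains.site_um == site)
                          & (trains.kcc2 == kc)].iloc[0]
        assert row(240.0, 0.0).d_ecl_mV > row(240.0, 1.0).d_ecl_mV
        assert row(240.0, 0.0).d_ecl_mV > row(0.0, 0.0).d_ecl_mV
        assert row(240.0, 0.0).ipsc_late_uA < row(240.0, 0.0).ipsc_first_uA

    def test_soma_insensitive_to_kcc2_removal(self, trains):
        soma = trains[trains.site_um == 0.0]
        i1 = soma[soma.kcc2 == 1.0].ipsc_first_uA.iloc[0]
        i0 = soma[soma.kcc2 == 0.0].ipsc_first_uA.iloc[0]
        assert i1 == pytest.approx(i0, rel=0.15)


class TestHCO3Tradeoff:
    DUR = 8000.0

    def test_cl_only_receptor_never_inverts(self):
        out, rec = P.protocol_hco3_tradeoff("no_hco3", g_nS=2.0,
                                            duration_ms=self.DUR)
        pop = rec.pop_current.shape[1]
        # with the held-open conductance in a window, the site current is
        # the Cl- term only; reconstruct it from E_Cl and V
        i_cl = (0.8 * 2.0 * 1e-6) * (out.v - out.e_cl)
        late = i_cl[out.t_ms > self.DUR / 2]
        assert late.min() > -1e-9         # decays toward zero, no inversion

    def test_reversal_shifts_are_opposite(self):
        out, _ = P.protocol_hco3_tradeoff("standard", g_nS=2.0,
                                          duration_ms=self.DUR)
        d_ecl = out.e_cl.iloc[-1] - out.e_cl.iloc[0]
        d_ehco3 = out.e_hco3.iloc[-1] - out.e_hco3.iloc[0]
        assert d_ecl > 0.5                # E_Cl collapses upward
        assert d_ehco3 < 0.0              # E_HCO3 drifts down slowly

    def test_clamping_hco3_exacerbates_ecl_shift(self):
        std, _ = P.protocol_hco3_tradeoff("standard", g_nS=2.0,
                                          duration_ms=self.DUR)
        clamped, _ = P.protocol_hco3_tradeoff("hco3_clamped", g_nS=2.0,
                                              duration_ms=self.DUR)
        d_std = std.e_cl.iloc[-1] - std.e_cl.iloc[0]
        d_cl = clamped.e_cl.iloc[-1] - clamped.e_cl.iloc[0]
        assert d_cl > d_std

    def test_acid_load_lowers_ecl_only_with_exchanger(self):
        with_ex, _ = P.protocol_hco3_tradeoff("acid_load",
                                              duration_ms=9000.0)
        no_ex, _ = P.protocol_hco3_tradeoff("acid_load", clhco3_scale=0.0,
                                            duration_ms=9000.0)
        # remove the exchanger by overriding after variant setup
        sel = (with_ex.t_ms > 2000.0) & (with_ex.t_ms < 7000.0)
        dip_with = (with_ex.e_cl[sel].min() - with_ex.e_cl.iloc[0])
        dip_without = (no_ex.e_cl[sel].min() - no_ex.e_cl.iloc[0])
        assert dip_with < dip_without - 0.3   # hyperpolarizing E_Cl dip


class TestPotassiumCoupling:
    def test_heavy_load_ko_scales_with_kcc2_and_tau(self):
        df = P.protocol_heavy_load_ko(kcc2_scales=(0.1, 4.0),
                                      tau_fh_values=(100.0, 200.0),
                                      g_nS=5.0)
        d100 = df[df.tau_fh == 100.0].set_index("kcc2").ko_peak
        assert d100[4.0] > d100[0.1]      # more KCC2 -> more K+ outside
        d01 = df[df.kcc2 == 4.0].set_index("tau_fh").ko_peak
        assert d01[200.0] > d01[100.0]    # slower clearance -> higher peak


class TestSpikeModulatingChannels:
    @pytest.fixture(scope="class")
    def soma(self):
        return build_cell(GeometryConfig(n_primary_dendrites=0,
                                         include_axon=False))

    def _rate(self, soma, **kw):
        cfg = SimConfig(duration=3000.0, record_interval=10.0, init="rest",
                        hh_scale=30.0,
                        current_injections=[(0, 0.15, 200.0, 3000.0)], **kw)
        return run(cfg, soma).spikes[0]

    def test_ahp_decreases_and_nap_increases_firing(self, soma):
        base = self._rate(soma)
        assert base > 50                  # sustained firing baseline
        assert self._rate(soma, ahp=True) < base
        assert self._rate(soma, nap=True) > base


class TestFocalAsymmetry:
    def test_no_interaction_across_primary_dendrites(self):
        cell = build_cell(GeometryConfig(n_primary_dendrites=2,
                                         comps_per_dendrite=20,
                                         dend_comp_length=10.0,
                                         uniform_dend_diam=1.0))
        same = P.protocol_focal_interaction(separations_um=(30,),
                                            kcc2_scales=(1.0,),
                                            same_dendrite=True, cell=cell,
                                            duration_ms=2000.0)
        other = P.protocol_focal_interaction(separations_um=(30,),
                                             kcc2_scales=(1.0,),
                                             same_dendrite=False, cell=cell,
                                             duration_ms=2000.0)
        assert same.d_cl_mM.iloc[0] > 3.0 * abs(other.d_cl_mM.iloc[0])
        assert same.d_cl_mM.iloc[0] > 0.1

    def test_centripetal_spread_steeper_toward_soma(self):
        cell = P.long_dendrite_cell()
        prof, summ, rec = P.protocol_focal_gradient(distance_um=50.0,
                                                    cell=cell,
                                                    duration_ms=2000.0)
        x = prof.distance_um.values
        elev = prof.elevation_mM.values
        xs = cell.path_distance_um[summ["syn_comp"]]
        # decay length on each side: distance to half of peak elevation
        def half_width(side):
            xi, ei = x[side], elev[side]
            order = np.argsort(np.abs(xi - xs))
            for idx in order:
                if ei[idx] < 0.5 * elev.max():
                    return abs(xi[idx] - xs)
            return np.inf
        toward = half_width(x < xs)
        away = half_width(x > xs)
        assert toward < away              # soma acts as a sink


class TestAISNKCC1:
    def test_ais_chloride_gradient_stays_local(self):
        """NKCC1 confined to the AIS elevates axonal [Cl-]i without the
        gradient extending into the dendrites."""
        df = P.protocol_ais_nkcc1(nkcc1_levels=(0.0, 1.0),
                                  kcc2_levels=(1.0,), noise=False,
                                  duration_ms=6000.0)
        from chloridesim.model_core import AIS
        ais = df[df.kind == AIS].set_index("nkcc1").cl_mM
        assert ais[1.0] > ais[0.0] + 0.5
        distal = df[df.distance_um > 150].groupby("nkcc1").cl_mM.mean()
        assert abs(distal[1.0] - distal[0.0]) < 0.3


class TestHeldOpenConvergence:
    def test_steady_level_and_rate_scale_with_distance(self):
        """With receptors held open on a tapered dendrite, E_Cl converges
        to a higher steady level, and faster, at more distal (thinner)
        sites -- the surface-to-volume ratio sets both the load per
        volume and the local clearance rate."""
        cell = build_cell(GeometryConfig(n_primary_dendrites=1,
                                         comps_per_dendrite=40,
                                         dend_comp_length=5.0))
        df = P.protocol_held_open_convergence(sites_um=(50.0, 190.0),
                                              kcc2_scales=(1.0,),
                                              duration_ms=8000.0,
                                              cell=cell)
        d = df.set_index("site_um")
        assert d.fit_ok.all()
        assert d.loc[190.0].e_cl_ss > d.loc[50.0].e_cl_ss + 0.5
        assert d.loc[190.0].tau_s < d.loc[50.0].tau_s
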
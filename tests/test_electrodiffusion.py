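"""Longitudinal/radial Nernst-Planck operators and the FH shell."""

import math

import numpy as np
import pytest

from chloridesim.constants import DEFAULT_CONSTANTS
from chloridesim.electrodiffusion import (DiffusionParams,
                                          cross_section_fractions,
                                          radial_operator,
                                          radial_update_matrix,
                                          longitudinal_step, radial_step,
                                          fh_shell_step, DiffusionGeometry,
                                          build_diffusion_geometry)
from chloridesim.model_core import build_cell, GeometryConfig

D_CL = 2.03e-5


def chain_geometry(n, dx_cm=1e-4, radius_cm=0.5e-4, n_annuli=1):
    """Unbranched uniform chain (parent = previous compartment)."""
    parent = np.arange(-1, n - 1, dtype=np.int64)
    area = math.pi * radius_cm ** 2
    vol = area * dx_cm
    f = cross_section_fractions(n_annuli)
    vol_ann = np.tile(vol * f, (n, 1))
    a_edge = np.full(n, area); a_edge[0] = 0.0
    dist = np.full(n, dx_cm); dist[0] = 1.0
    return DiffusionGeometry(parent, vol_ann, vol * 0.25 * np.ones(n),
                             a_edge, dist, f, np.empty((0, n, 1, 1)))


class TestCrossSections:
    def test_equal_thickness_ring_fractions(self):
        f = cross_section_fractions(4)
        assert np.allclose(f, np.array([7, 5, 3, 1]) / 16)
        assert f.sum() == pytest.approx(1.0)


class TestLongitudinal:
    def test_uniform_state_is_stationary(self):
        geom = chain_geometry(10)
        c = np.full((10, 1), 6.0)
        v = np.full(10, -70.0)
        out = longitudinal_step(c, v, 0.05, geom, D_CL)
        assert np.allclose(out, c, atol=1e-14)

    def test_mass_conservation_long_run(self):
        geom = chain_geometry(21)
        rng = np.random.default_rng(0)
        c = rng.uniform(1, 10, size=(21, 1))
        v = rng.uniform(-90, -50, size=21)
        total0 = (c[:, 0] * geom.vol_ann[:, 0]).sum()
        for _ in range(20000):
            c = longitudinal_step(c, v, 0.05, geom, D_CL)
        total = (c[:, 0] * geom.vol_ann[:, 0]).sum()
        assert abs(total - total0) / total0 < 1e-12

    def test_point_load_matches_heat_kernel(self):
        # 1-D diffusion of a point load on a sealed 201-um cable vs the
        # closed-form Gaussian at t = 50 ms (domain wide enough that the
        # boundaries are beyond 7 sigma)
        n, dx = 201, 1e-4
        geom = chain_geometry(n, dx_cm=dx)
        c = np.zeros((n, 1)); c[n // 2, 0] = 1.0
        v = np.zeros(n)
        dt, t_end = 0.05, 50.0
        for _ in range(int(t_end / dt)):
            c = longitudinal_step(c, v, dt, geom, D_CL, drift=False)
        x = (np.arange(n) - n // 2) * dx
        sig2 = 2 * D_CL * t_end * 1e-3
        gauss = np.exp(-x ** 2 / (2 * sig2))
        gauss *= dx / math.sqrt(2 * math.pi * sig2)
        rms = np.sqrt(np.mean((c[:, 0] - gauss) ** 2))
        assert rms / gauss.max() < 0.02

    def test_drift_direction_against_two_compartment_oracle(self):
        # anion (z = -1) drifts toward the depolarized side
        geom = chain_geometry(2)
        c = np.full((2, 1), 6.0)
        v = np.array([-70.0, -60.0])   # compartment 1 depolarized
        out = longitudinal_step(c, v, 0.05, geom, D_CL, z=-1.0)
        assert out[1, 0] > 6.0 and out[0, 0] < 6.0
        # flux reverses with the potential gradient
        out2 = longitudinal_step(c, v[::-1].copy(), 0.05, geom, D_CL, z=-1.0)
        assert out2[1, 0] < 6.0
        # and matches the hand-computed Nernst-Planck drift magnitude:
        # flux into compartment 1 = D A/d * z * cbar * (V_0 - V_1)/(RT/F)
        rtf = DEFAULT_CONSTANTS.RT_over_F
        q = (D_CL * 1e-3 * geom.a_edge[1] / geom.dist_edge[1]
             * (-1.0) * 6.0 * (-10.0) / rtf * 0.05)
        assert out[1, 0] - 6.0 == pytest.approx(q / geom.vol_ann[1, 0],
                                                rel=1e-12)


class TestRadial:
    def test_operator_conserves_mass(self):
        L = radial_operator(0.5e-4, 20e-4, D_CL)
        f = cross_section_fractions(4)
        assert np.allclose(f @ L, 0.0, atol=1e-12)

    def test_update_matrix_stationary_on_uniform(self):
        M = radial_update_matrix(0.5e-4, 20e-4, D_CL, 0.05)
        assert np.allclose(M @ np.full(4, 3.0), 3.0, atol=1e-10)

    def test_monotone_equilibration_to_weighted_mean(self):
        M = radial_update_matrix(0.5e-4, 20e-4, D_CL, 0.05)
        f = cross_section_fractions(4)
        c = np.array([10.0, 6.0, 6.0, 6.0])     # membrane-only influx
        mean = float(f @ c)
        prev_spread = c.max() - c.min()
        for _ in range(200):
            c = radial_step(c, M)
            spread = c.max() - c.min()
            assert spread <= prev_spread + 1e-12
            prev_spread = spread
        assert np.allclose(c, mean, atol=1e-6)
        assert f @ c == pytest.approx(mean, rel=1e-12)

    def test_submillisecond_relaxation_in_thin_dendrite(self):
        # r^2/D for a 1-um-diameter compartment is far below tau_FH
        M = radial_update_matrix(0.5e-4, 20e-4, D_CL, 0.05)
        c = np.array([10.0, 6.0, 6.0, 6.0])
        target = float(cross_section_fractions(4) @ c)
        spread0 = c.max() - c.min()
        t, dt = 0.0, 0.05
        while c.max() - c.min() > spread0 / 2:
            c = radial_step(c, M)
            t += dt
        assert t < 1.0               # half-time below 1 ms << 100 ms


class TestFHShell:
    def test_efold_relaxation_at_100ms(self):
        conc = np.array([4.0])       # bath + 1 mM perturbation
        bath = np.array([3.0])
        t, dt = 0.0, 0.05
        while conc[0] - bath[0] > 1.0 / math.e:
            conc = fh_shell_step(conc, np.zeros(1), dt, bath, tau_fh=100.0)
            t += dt
        assert t == pytest.approx(100.0, rel=0.01)

    def test_steady_state_elevation(self):
        # constant efflux J (already per shell volume) -> bath + J*tau
        bath = np.array([3.0])
        conc = np.array([3.0])
        j = np.array([0.002])        # mM/ms
        for _ in range(20000):
            conc = fh_shell_step(conc, j, 0.05, bath, tau_fh=100.0)
        assert conc[0] - bath[0] == pytest.approx(0.002 * 100.0, rel=1e-4)


class TestGeometryBuilder:
    def test_shell_volume_ratio_and_annuli(self, default_cell):
        geom = build_diffusion_geometry(default_cell, 0.05)
        vol = default_cell.volume_cm3
        assert np.allclose(geom.vol_ann.sum(axis=1), vol, rtol=1e-12)
        assert np.allclose(geom.shell_vol, 0.25 * vol, rtol=1e-12)

    def test_cfl_violation_rejected(self):
        cell = build_cell(GeometryConfig(n_primary_dendrites=1,
                                         comps_per_dendrite=4,
                                         dend_comp_length=0.3,
                                         include_axon=False))
        with pytest.raises(ValueError, match="unstable"):
            build_diffusion_geometry(cell, 0.05)
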
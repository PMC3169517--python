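"""Pumps and electroneutral cotransporters.

The Na+-K+-ATPase is the only electrogenic transporter (3 Na+ out : 2 K+
in, net one positive charge out per cycle).  KCC2, NKCC1 and the
Cl-/HCO3- exchanger are strictly electroneutral: they move moles, not net
charge, and are driven by differences of equilibrium potentials.

All three electroneutral carriers use the same odd-symmetric saturating
law

    J = I_max * DF / (|DF| + V_half)

expressed as a Cl- current equivalent (mA/cm^2): J reverses sign with the
driving force DF and reaches half of I_max at DF = V_half.  Mole fluxes
are the current equivalents divided by F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

from .constants import FARADAY, DEFAULT_CONSTANTS

__all__ = [
    "PumpParams", "KCC2Params", "NKCC1Params", "ClHCO3Params",
    "nak_pump", "kcc2_flux", "nkcc1_flux", "cl_hco3_exchange",
    "MA_CM2_TO_MOL", "saturating_rate",
]

#: 1 mA/cm^2 of monovalent-ion current = this many mol/(cm^2 s)
MA_CM2_TO_MOL = 1e-3 / FARADAY


@dataclass
class PumpParams:
    """Na+-K+-ATPase parameters.

    ``I_NaK_max`` (mA/cm^2, Na+ current scale) is not printed for the
    source model; the integration engine calibrates it at setup so that
    the pump exactly balances the Na+ leak at the initial concentrations
    (the default here is the calibrated somatic value's order of
    magnitude).  Saturation follows the Livshitz/Decker formulation:
    Michaelis factors in [K+]o and [Na+]i and a voltage factor
    f_v = 1 / (1 + 0.1245 e^{-0.1 VF/RT} + 0.0365 sigma e^{-VF/RT}),
    sigma = (e^{[Na+]o / 67.3} - 1) / 7.
    """
    I_NaK_max: float = 0.006   # mA/cm^2
    K_m_Ko: float = 1.5        # mM
    K_m_Nai: float = 10.0      # mM
    Na_Half: float = 20.0      # mM
    Na_o: float = 45.0         # mM, enters the voltage factor only


@dataclass
class KCC2Params:
    I_Cl_max: float = 0.3      # mA/cm^2 at 100% activity
    V_half: float = 40.0       # mV
    activity_scale: float = 1.0


@dataclass
class NKCC1Params:
    I_Cl_max: float = 0.3
    V_half: float = 40.0       # not printed; same as KCC2 by default
    activity_scale: float = 1.0


@dataclass
class ClHCO3Params:
    I_Cl_max: float = 0.1
    V_half: float = 50.0
    activity_scale: float = 1.0


@njit(cache=True)
def saturating_rate(df: float, i_max: float, v_half: float) -> float:
    """Odd-symmetric Michaelis rate I_max * DF / (|DF| + V_half)."""
    return i_max * df / (abs(df) + v_half)


@njit(cache=True)
def pump_rate(v: float, k_o: float, na_i: float, i_max: float,
              km_ko: float, km_nai: float, na_half: float,
              na_o: float, rt_over_f: float) -> float:
    """Na+-K+-ATPase cycle rate as a Na+ current density (same units as
    i_max; the Na+ current is 3x, wait -- see nak_pump; this is the
    saturable scale rho such that I_Na = 3*rho, I_K = -2*rho)."""
    sigma = (math.exp(na_o / 67.3) - 1.0) / 7.0
    vf = v / rt_over_f
    f_v = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vf)
                 + 0.0365 * sigma * math.exp(-vf))
    f_k = k_o / (k_o + km_ko)
    # Na+ activation: cubic half-saturation at Na_Half (three Na+ binding
    # sites) times the Livshitz Michaelis term in K_m_Nai.  The steep Na+
    # dependence (logarithmic gain ~3 at rest) is what lets the pump ramp
    # against synaptic Na+ loads far exceeding the resting leak.
    r = na_i / (na_i + na_half)
    f_na = r * r * r / (1.0 + (km_nai / na_i) ** 2)
    return i_max * f_v * f_k * f_na


def nak_pump(v: float, k_o: float, na_i: float,
             params: PumpParams = PumpParams()):
    """Pump currents (mA/cm^2, positive outward): ``(I_Na, I_K, I_net)``.

    Stoichiometry is fixed at 3 Na+ out : 2 K+ in, so I_K = -(2/3) I_Na
    and the net electrogenic current is (1/3) I_Na, outward.
    """
    if k_o <= 0 or na_i <= 0:
        raise ValueError("concentrations must be positive")
    rho = pump_rate(v, k_o, na_i, params.I_NaK_max, params.K_m_Ko,
                    params.K_m_Nai, params.Na_Half, params.Na_o,
                    DEFAULT_CONSTANTS.RT_over_F)
    i_na = 3.0 * rho
    return i_na, -2.0 * rho, rho


def kcc2_flux(e_cl: float, e_k: float,
              params: KCC2Params = KCC2Params()):
    """KCC2 mole fluxes, mol/(cm^2 s), positive outward: ``(J_Cl, J_K, I_net)``.

    Driving force DF = E_Cl - E_K; Cl- and K+ leave together (1:1), so the
    net electrical current is exactly zero.  DF < 0 reverses both fluxes.
    """
    df = e_cl - e_k
    j = saturating_rate(df, params.activity_scale * params.I_Cl_max,
                        params.V_half) * MA_CM2_TO_MOL
    return j, j, 0.0


def nkcc1_flux(e_cl: float, e_k: float, e_na: float,
               params: NKCC1Params = NKCC1Params()):
    """NKCC1 mole fluxes, mol/(cm^2 s), positive inward:
    ``(J_Cl, J_Na, J_K, I_net)``.

    The transporter reverses where E_Cl equals E_NKCC1 = (E_K + E_Na)/2.
    Stoichiometry 1 Na+ : 1 K+ : 2 Cl- (electroneutral): the Na+ and K+
    fluxes are each half the Cl- flux.
    """
    e_rev = 0.5 * (e_k + e_na)
    j_cl = saturating_rate(e_rev - e_cl,
                           params.activity_scale * params.I_Cl_max,
                           params.V_half) * MA_CM2_TO_MOL
    return j_cl, 0.5 * j_cl, 0.5 * j_cl, 0.0


def cl_hco3_exchange(e_cl: float, e_hco3: float,
                     params: ClHCO3Params = ClHCO3Params()):
    """Cl-/HCO3- exchanger mole fluxes, mol/(cm^2 s), positive outward:
    ``(J_Cl, J_HCO3, I_net)`` with J_HCO3 = -J_Cl (1:1 anion swap).

    DF = E_HCO3 - E_Cl.  In the normal resting state (E_HCO3 > ... i.e.
    DF < 0 with E_Cl ~ -80 mV, E_HCO3 ~ -14 mV is positive; the exchanger
    then moves Cl- in and HCO3- out, depolarizing E_Cl and
    hyperpolarizing E_HCO3, and reverses when E_HCO3 drops below E_Cl.
    """
    df = e_hco3 - e_cl
    j_cl_out = saturating_rate(-df, params.activity_scale * params.I_Cl_max,
                               params.V_half) * MA_CM2_TO_MOL
    return j_cl_out, -j_cl_out, 0.0


def calibrate_pump(e_k: float, e_na: float, k_o: float, na_i: float,
                   gk_over_gna: float = 5.0,
                   params: PumpParams = PumpParams(),
                   rt_over_f: float = DEFAULT_CONSTANTS.RT_over_F):
    """Resting potential and pump scale balancing the leaks.

    With K+ and Na+ leak conductances in ratio r = gK/gNa, requiring (a)
    zero net membrane current and (b) zero net Na+ flux (pump efflux 3*rho
    equal to the leak influx) at rest fixes both the resting potential

        V0 = (3 r E_K + 2 E_Na) / (3 r + 2)

    and the pump scale.  K+ is then automatically near balance (pump
    import is 2/3 of the Na+ leak), the small residual being absorbed by
    the extracellular-shell bath exchange.  Returns ``(V0, lam)`` where
    ``lam * gNa_leak`` (mV * mS/cm^2 = uA/cm^2) is the compartment's
    maximal pump rate rho_max, i.e. pump I_NaK_max density = lam * gNa_leak.
    """
    r = gk_over_gna
    v0 = (3.0 * r * e_k + 2.0 * e_na) / (3.0 * r + 2.0)
    f = pump_rate(v0, k_o, na_i, 1.0, params.K_m_Ko, params.K_m_Nai,
                  params.Na_Half, params.Na_o, rt_over_f)
    lam = (e_na - v0) / (3.0 * f)
    return v0, lam
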
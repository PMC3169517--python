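"""Intracellular carbonate/phosphate chemistry and proton extrusion.

Two buffering reactions are modeled:

* carbonic-anhydrase-catalyzed CO2 hydration,
  ``CO2 + H2O <-> H+ + HCO3-`` with equilibrium constant
  ``K_eq = [H+][HCO3-]/[CO2] = 10^-6.35 M`` and forward rate constant
  10^6 s^-1.  Dissolved CO2 is held constant (gas exchange across the
  membrane is much faster than ionic fluxes), so the product
  ``[H+][HCO3-]`` relaxes to the constant ``K_eq * [CO2]``.
* phosphate buffering, ``H+ + HPO4^2- <-> H2PO4-`` with
  ``K_a = [H+][HPO4]/[H2PO4] = 10^-pK`` (pK 7.2); total phosphate is
  conserved exactly.

Because the CO2 hydration rate constant makes the subsystem far stiffer
than the 0.05-ms integration step, the engine advances the chemistry with
an analytic equilibrium projection each step (:func:`equilibrate`): the
two reaction extents conserve total phosphate P and the combination
``B = [HCO3-] - [H+] - [H2PO4-]``, and the projected state is the unique
positive root of

    K1'/H - H - P*H/(H + K_a) = B,       K1' = K_eq [CO2].

The explicit rate law is still available (:func:`carbonic_anhydrase_step`,
internally sub-stepped) for studying relaxation kinetics.

Proton extrusion uses a Na+/H+ exchanger with the generic saturating
transporter law driven by E_Na - E_H (electroneutral 1:1 swap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from numba import njit

from .constants import FARADAY, DEFAULT_CONSTANTS, EXTRACELLULAR_PH
from .transport import saturating_rate, MA_CM2_TO_MOL

__all__ = [
    "ChemistryParams", "carbonic_anhydrase_step", "phosphate_buffer_step",
    "na_h_exchange", "equilibrate", "ph_from_h",
]


def ph_from_h(h_molar: float) -> float:
    return -math.log10(h_molar)


@dataclass
class ChemistryParams:
    """Constants of the intracellular buffering system (concentrations M).

    ``co2`` is back-computed once so that the printed initial state
    ([HCO3-]i = 15 mM at the phosphate-equilibrium pH 7.2) is an exact
    chemical equilibrium.
    """
    K_eq_CA: float = 10.0 ** -6.35        # M
    k_forward: float = 1e6                # 1/s, CO2 hydration
    pK_phosphate: float = 7.2
    phosphate_total: float = 60e-3        # M (30 mM + 30 mM)
    I_H_max: float = 0.03                 # mA/cm^2
    V_half_H: float = 10.0                # mV
    pH_extracellular: float = EXTRACELLULAR_PH
    hco3_init: float = 15e-3              # M
    ph_init: float = 7.2                  # = pK at equal phosphate split

    @property
    def h_init(self) -> float:
        return 10.0 ** -self.ph_init

    @property
    def co2(self) -> float:
        """Fixed dissolved CO2 (M) pinning the initial state at equilibrium."""
        return self.h_init * self.hco3_init / self.K_eq_CA

    @property
    def K1_prime(self) -> float:
        """Equilibrium value of [H+][HCO3-] (M^2) at fixed CO2."""
        return self.K_eq_CA * self.co2

    @property
    def K_a(self) -> float:
        return 10.0 ** -self.pK_phosphate

    @property
    def h_out(self) -> float:
        return 10.0 ** -self.pH_extracellular


def carbonic_anhydrase_step(hco3_mM: float, h_M: float, dt_ms: float,
                            params: ChemistryParams = ChemistryParams()):
    """Explicit integration of the CO2 hydration rate law over dt.

    net rate = k_f [CO2] - k_r [H+][HCO3-],  k_r = k_f / K_eq,

    producing equal increments of H+ and HCO3- (1:1).  Returns
    ``(d_hco3_mM, d_h_M)``.  The printed rate constants make the reaction
    relax within nanoseconds (k_r [H][HCO3] sum ~ 3e10 1/s), far below any
    usable explicit step, so the update integrates the exactly-linearized
    rate law: the reaction extent decays exponentially toward the
    equilibrium root at the linearized rate k_r ([H+]_eq + [HCO3-]_eq);
    for dt much smaller than that time constant this reduces to the raw
    Euler step of the rate law.
    """
    if hco3_mM <= 0 or h_M <= 0:
        raise ValueError("concentrations must be positive")
    kf = params.k_forward
    kr = kf / params.K_eq_CA
    hco3 = hco3_mM * 1e-3
    h = h_M
    t_s = dt_ms * 1e-3
    s = hco3 - h                       # conserved by the 1:1 reaction
    k1p = params.K1_prime              # = K_eq * [CO2]
    h_eq = 0.5 * (-s + math.sqrt(s * s + 4.0 * k1p))
    lam = kr * (2.0 * h_eq + s)        # linearized relaxation rate, 1/s
    decay = math.exp(-lam * t_s)
    h_new = h_eq + (h - h_eq) * decay
    hco3_new = hco3 + (h_new - h)
    return (hco3_new - hco3) * 1e3, h_new - h


def phosphate_buffer_step(h_M: float, h2po4_mM: float, hpo4_mM: float,
                          dt_ms: float = 0.0,
                          params: ChemistryParams = ChemistryParams()):
    """Fast equilibration of H+ + HPO4^2- <-> H2PO4-.

    The reaction is treated as instantaneous (its kinetics are diffusion
    limited, far below the integration step): the state jumps to the
    mass-action equilibrium that conserves total phosphate and total
    ``H+ + H2PO4-``.  Returns the updated ``(h_M, h2po4_mM, hpo4_mM)``.
    """
    if min(h_M, h2po4_mM, hpo4_mM) <= 0:
        raise ValueError("concentrations must be positive")
    ka = params.K_a
    p = (h2po4_mM + hpo4_mM) * 1e-3
    htot = h_M + h2po4_mM * 1e-3
    # H * (P - x) ... solve for free H with h2po4 = htot - H:
    #   H * (P - (htot - H)) = ka * (htot - H)
    b = p - htot + ka
    c = -ka * htot
    h = 0.5 * (-b + math.sqrt(b * b - 4.0 * c))
    h2po4 = htot - h
    hpo4 = p - h2po4
    return h, h2po4 * 1e3, hpo4 * 1e3


def na_h_exchange(e_na: float, e_h: float,
                  params: ChemistryParams = ChemistryParams(),
                  df_set: float = 0.0):
    """Na+/H+ exchanger mole fluxes, mol/(cm^2 s): ``(J_H_out, J_Na_in, I_net)``.

    Driving force DF = (E_Na - E_H) - df_set with the generic saturating
    law; one Na+ enters per H+ extruded, so the process is electroneutral.

    ``df_set`` is the exchanger's kinetic set point.  The full model runs
    with df_set equal to the resting value of E_Na - E_H (~52 mV), so the
    exchanger is silent at resting pH and activates in proportion to acid
    displacement -- the physiological behavior of NHE1, whose H+ modifier
    site switches it off near resting pH.  Without a set point the
    thermodynamic driving force alone would extrude protons (and load Na+
    at ~25 uA/cm^2, dwarfing the Na+ leak) continuously at rest,
    alkalinizing the cell toward pH ~8 -- incompatible with the stable
    initial state the model is built around.
    """
    j = saturating_rate(e_na - e_h - df_set, params.I_H_max,
                        params.V_half_H) * MA_CM2_TO_MOL
    return j, j, 0.0


@njit(cache=True)
def equilibrate(h: float, hco3: float, h2po4: float, hpo4: float,
                k1p: float, ka: float):
    """Project (H+, HCO3-, H2PO4-, HPO4^2-) [all M] onto the joint
    equilibrium of the carbonate (fixed CO2) and phosphate reactions.

    Conserves P = h2po4 + hpo4 and B = hco3 - h - h2po4 exactly and
    returns the unique positive solution of
    ``k1p/H - H - P H/(H + ka) = B`` (monotone in H -> Newton with a
    bisection fallback).
    """
    p = h2po4 + hpo4
    b = hco3 - h - h2po4
    x = h if h > 0.0 else 1e-8
    for _ in range(60):
        f = k1p / x - x - p * x / (x + ka) - b
        df = -k1p / (x * x) - 1.0 - p * ka / ((x + ka) * (x + ka))
        step = f / df
        xn = x - step
        if xn <= 0.0:
            xn = 0.5 * x
        if abs(xn - x) <= 1e-12 * x:
            x = xn
            break
        x = xn
    h_new = x
    hco3_new = k1p / h_new
    h2po4_new = p * h_new / (h_new + ka)
    hpo4_new = p - h2po4_new
    return h_new, hco3_new, h2po4_new, hpo4_new
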
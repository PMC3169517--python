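"""Physical constants and global unit conventions.

Internal unit system (used consistently by every module):

========================  =========
quantity                  unit
========================  =========
time                      ms
membrane potential        mV
concentration             mM  (H+ included; chemistry converts to M locally)
length (geometry)         cm
membrane current density  uA/cm^2
absolute conductance      mS   (1 nS = 1e-6 mS; mS * mV = uA)
conductance density       mS/cm^2
capacitance               uF/cm^2
amount                    mol, volume cm^3 (1 mol/cm^3 = 1e6 mM)
========================  =========

With these units a current density i (uA/cm^2) over a membrane patch of
area S (cm^2) changes the concentration of a species of valence z in a
volume Vol (cm^3) by

    dC[mM] = -i * S * dt[ms] * 1e-3 / (z * F * Vol)

which is the compartmental form of the concentration balance used by the
integration engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Faraday constant, C/mol
FARADAY = 96485.332
#: molar gas constant, J/(mol K)
GAS_CONSTANT = 8.31446


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic and passive-membrane constants.

    Attributes
    ----------
    F : Faraday constant (C/mol).
    R : gas constant (J/(mol K)).
    T : absolute temperature (K); 310 K = 37 C.
    C_m : specific membrane capacitance (uF/cm^2).
    R_a : axial (cytoplasmic) resistivity (Ohm cm) used for the cable
        coupling between compartments.
    """

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = 310.0
    C_m: float = 1.0
    R_a: float = 150.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage R*T/F in mV (~26.71 mV at 310 K)."""
        return 1e3 * self.R * self.T / self.F


DEFAULT_CONSTANTS = PhysicalConstants()

# Fixed extracellular pH (extracellular H+ is not a tracked species).
EXTRACELLULAR_PH = 7.4

# ---------------------------------------------------------------------------
# Species bookkeeping
# ---------------------------------------------------------------------------
# Intracellular state carries all eight species; the extracellular shell
# carries the first five (H+ and phosphates are intracellular only, the
# extracellular pH being held fixed).
SPECIES = ("Cl", "K", "Na", "Ca", "HCO3", "H", "H2PO4", "HPO4")
SHELL_SPECIES = ("Cl", "K", "Na", "Ca", "HCO3")

ICL, IK, INA, ICA, IHCO3, IH, IH2PO4, IHPO4 = range(8)

#: valence of each species, order as SPECIES
VALENCE = (-1.0, 1.0, 1.0, 2.0, -1.0, 1.0, -1.0, -2.0)

#: aqueous diffusion coefficients, 1e-5 cm^2/s units, order as SPECIES.
#: Cl/Na/K/H are the printed values; HCO3/Ca/phosphates are aqueous
#: literature defaults (configurable, excluded from quantitative checks).
DIFFUSION_1E5 = (2.03, 1.96, 1.33, 0.79, 1.18, 9.33, 0.85, 0.85)
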
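"""Cell geometry, domain types and equilibrium-potential computations.

The model neuron is a tree of cylindrical (possibly tapered) compartments
rooted at a single soma: by default three primary dendrites of ten serial
compartments each (30 dendritic compartments), an axon initial segment
(AIS) hanging off the soma, and a myelinated axon of ten internodes
separated by nodes of Ranvier.  Each compartment is subdivided into four
concentric annuli by the electrodiffusion operator.

Equilibrium potentials: :func:`nernst` for single-ion reversal potentials
and :func:`ghk_anion_reversal` for the GABA_A reversal, which mixes the
Cl- and HCO3- gradients with a 4:1 permeability ratio
(Goldman-Hodgkin-Katz, anion convention: intracellular activities in the
numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .constants import PhysicalConstants, DEFAULT_CONSTANTS

__all__ = [
    "Compartment",
    "CellModel",
    "GeometryConfig",
    "build_cell",
    "nernst",
    "ghk_anion_reversal",
    "load_geometry_config",
]

# compartment kind codes
SOMA, DENDRITE, AIS, AXON_NODE, AXON_INTERNODE = range(5)
KIND_NAMES = {
    SOMA: "soma",
    DENDRITE: "dendrite",
    AIS: "AIS",
    AXON_NODE: "axon_node",
    AXON_INTERNODE: "axon_internode",
}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


# ---------------------------------------------------------------------------
# equilibrium potentials
# ---------------------------------------------------------------------------

def nernst(z: int, conc_in: float, conc_out: float,
           constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Nernst equilibrium potential in mV.

    E = (RT / zF) * ln([out]/[in])

    Parameters
    ----------
    z : ion valence (nonzero integer).
    conc_in, conc_out : concentrations on the two sides of the membrane
        (any common unit, strictly positive).

    Raises
    ------
    ValueError : for non-positive concentrations or z == 0.  Concentrations
        are never silently clipped.
    """
    if z == 0:
        raise ValueError("valence must be nonzero")
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError(
            f"concentrations must be positive (got in={conc_in}, out={conc_out})")
    return constants.RT_over_F / z * math.log(conc_out / conc_in)


def ghk_anion_reversal(cl_in: float, cl_out: float,
                       hco3_in: float, hco3_out: float,
                       perm_ratio_cl_to_hco3: float = 4.0,
                       constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """GABA_A reversal potential (mV) from the GHK voltage equation.

    For two monovalent anions with permeabilities P_Cl and P_HCO3,

        E = (RT/F) * ln( (P_Cl [Cl]_i + P_HCO3 [HCO3]_i)
                         / (P_Cl [Cl]_o + P_HCO3 [HCO3]_o) )

    ``perm_ratio_cl_to_hco3`` is P_Cl / P_HCO3 (4 for the GABA_A channel).
    The result always lies strictly between the Cl- and HCO3- Nernst
    potentials when those differ.
    """
    if min(cl_in, cl_out, hco3_in, hco3_out) <= 0:
        raise ValueError("concentrations must be positive")
    if perm_ratio_cl_to_hco3 <= 0:
        raise ValueError("permeability ratio must be positive")
    p = perm_ratio_cl_to_hco3
    return constants.RT_over_F * math.log(
        (p * cl_in + hco3_in) / (p * cl_out + hco3_out))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    """One cable section.

    ``diameter_proximal``/``diameter_distal`` describe a linear taper
    (frustum); membrane area uses the frustum lateral surface.
    ``path_distance_to_soma`` is measured center-to-center (sum of the
    parent's path distance plus the two half-lengths).
    """

    id: int
    kind: int
    length: float                 # um
    diameter_proximal: float      # um
    diameter_distal: float        # um
    parent_id: Optional[int]
    path_distance_to_soma: float  # um
    n_annuli: int = 4

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"compartment {self.id}: length must be > 0")
        if self.diameter_proximal <= 0 or self.diameter_distal <= 0:
            raise ValueError(f"compartment {self.id}: diameters must be > 0")

    @property
    def kind_name(self) -> str:
        return KIND_NAMES[self.kind]

    @property
    def mean_radius(self) -> float:
        """Mean radius in um."""
        return (self.diameter_proximal + self.diameter_distal) / 4.0

    @property
    def membrane_area(self) -> float:
        """Frustum lateral surface in um^2."""
        r1 = self.diameter_proximal / 2.0
        r2 = self.diameter_distal / 2.0
        slant = math.sqrt(self.length ** 2 + (r1 - r2) ** 2)
        return math.pi * (r1 + r2) * slant

    @property
    def volume(self) -> float:
        """Frustum volume in um^3."""
        r1 = self.diameter_proximal / 2.0
        r2 = self.diameter_distal / 2.0
        return math.pi * self.length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


# Per-kind mechanism surface densities (mS/cm^2) and synapse densities
# (synapses per 100 um^2).  Dendritic leak densities depend on proximal vs
# distal position and are resolved in build_cell.  The AIS leak and tonic
# densities are not printed for the source model; somatic values are used.
DENSITY_TABLE = {
    "gbar_Na": {SOMA: 1.2, DENDRITE: 1.2, AIS: 12.0, AXON_NODE: 0.0,
                AXON_INTERNODE: 0.0},
    "gK_leak": {SOMA: 0.02, AIS: 0.02, AXON_NODE: 15.0,
                AXON_INTERNODE: 0.02e-3},
    "gNa_leak": {SOMA: 0.004, AIS: 0.004, AXON_NODE: 3.0,
                 AXON_INTERNODE: 0.004e-3},
    "gGABA_leak": {SOMA: 0.003, AIS: 0.003, AXON_NODE: 2.3,
                   AXON_INTERNODE: 0.003e-3},
    "syn_gaba_per_100um2": {SOMA: 40.0, DENDRITE: 12.0, AIS: 60.0,
                            AXON_NODE: 0.0, AXON_INTERNODE: 0.0},
    "syn_ampa_per_100um2": {SOMA: 0.0, DENDRITE: 60.0, AIS: 0.0,
                            AXON_NODE: 0.0, AXON_INTERNODE: 0.0},
}
DENDRITE_LEAKS = {  # (gK_leak, gNa_leak, gGABA_leak)
    "proximal": (0.03, 0.006, 0.0045),
    "distal": (0.1, 0.02, 0.015),
}
#: gbar_K (delayed rectifier) relative to gbar_Na; the source model family
#: uses 120:100 pS/um^2.
GBAR_K_RATIO = 10.0 / 12.0


@dataclass
class GeometryConfig:
    """Parametric geometry of the default cell (lengths/diameters in um)."""

    n_primary_dendrites: int = 3
    comps_per_dendrite: int = 10
    dend_comp_length: float = 20.0
    dend_diam_proximal: float = 2.0
    dend_diam_distal: float = 0.5
    uniform_dend_diam: Optional[float] = None  # overrides the taper
    soma_diameter: float = 20.0
    soma_length: float = 20.0
    ais_length: float = 20.0
    ais_diameter: float = 1.0
    include_axon: bool = True
    n_internodes: int = 10
    internode_length: float = 100.0
    internode_diameter: float = 1.0
    node_length: float = 1.0
    node_diameter: float = 1.0
    n_annuli: int = 4
    proximal_cutoff: float = 100.0  # dendritic path distance splitting
    #                                 proximal from distal leak densities


class CellModel:
    """Compartment tree plus per-compartment mechanism and synapse tables.

    Attributes
    ----------
    compartments : list[Compartment]
        Ordered so that every parent precedes its children (the soma is
        index 0), which the cable solver relies on.
    mechanism_densities : dict[str, np.ndarray]
        Surface densities (mS/cm^2) per compartment: gbar_Na, gbar_K,
        gK_leak, gNa_leak, gGABA_leak.
    synapse_counts : dict[str, np.ndarray]
        Integer synapse counts per compartment for "GABA_A" and "AMPA"
        (density x membrane area, rounded to nearest, minimum 1 wherever
        the density is positive).
    """

    def __init__(self, compartments: list[Compartment],
                 mechanism_densities: dict[str, np.ndarray],
                 synapse_counts: dict[str, np.ndarray],
                 primary_dendrite_count: int,
                 config: GeometryConfig):
        self.compartments = compartments
        self.mechanism_densities = mechanism_densities
        self.synapse_counts = synapse_counts
        self.primary_dendrite_count = primary_dendrite_count
        self.config = config
        self._validate()

    # -- derived arrays ----------------------------------------------------
    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    @property
    def kind(self) -> np.ndarray:
        return np.array([c.kind for c in self.compartments], dtype=np.int64)

    @property
    def parent(self) -> np.ndarray:
        return np.array([-1 if c.parent_id is None else c.parent_id
                         for c in self.compartments], dtype=np.int64)

    @property
    def length_cm(self) -> np.ndarray:
        return np.array([c.length * 1e-4 for c in self.compartments])

    @property
    def radius_cm(self) -> np.ndarray:
        return np.array([c.mean_radius * 1e-4 for c in self.compartments])

    @property
    def area_cm2(self) -> np.ndarray:
        return np.array([c.membrane_area * 1e-8 for c in self.compartments])

    @property
    def volume_cm3(self) -> np.ndarray:
        return np.array([c.volume * 1e-12 for c in self.compartments])

    @property
    def path_distance_um(self) -> np.ndarray:
        return np.array([c.path_distance_to_soma for c in self.compartments])

    def dendritic_ids(self) -> np.ndarray:
        return np.where(self.kind == DENDRITE)[0]

    def compartment_at_distance(self, distance_um: float,
                                dendrite: int = 0) -> int:
        """Index of the dendritic compartment of one primary dendrite whose
        center is closest to ``distance_um`` from the soma."""
        ids = [c.id for c in self.compartments
               if c.kind == DENDRITE and getattr(c, "_branch", -1) == dendrite]
        if not ids:
            raise ValueError(f"no compartments on dendrite {dendrite}")
        d = self.path_distance_um[ids]
        return int(ids[int(np.argmin(np.abs(d - distance_um)))])

    # -- invariants --------------------------------------------------------
    def _validate(self) -> None:
        kinds = self.kind
        if int(np.sum(kinds == SOMA)) != 1:
            raise ValueError("exactly one compartment must be the soma")
        parent = self.parent
        if parent[0] != -1 or kinds[0] != SOMA:
            raise ValueError("compartment 0 must be the soma root")
        for i in range(1, self.n_comp):
            if not (0 <= parent[i] < i):
                raise ValueError(
                    "compartment graph must be a tree rooted at the soma "
                    "with parents preceding children")
        for name, arr in self.mechanism_densities.items():
            if np.any(arr < 0):
                raise ValueError(f"negative density in {name}")


def _dendrite_leak_band(path_distance: float, cutoff: float) -> str:
    return "proximal" if path_distance <= cutoff else "distal"


def build_cell(config: GeometryConfig | dict | None = None) -> CellModel:
    """Construct the default parametric cell.

    Topology: soma (index 0); ``n_primary_dendrites`` unbranched dendrites
    of ``comps_per_dendrite`` serial compartments; an AIS child of the
    soma; then an alternating internode/node chain.  Mechanism densities
    and synapse counts are populated from the per-kind tables.
    """
    if config is None:
        config = GeometryConfig()
    elif isinstance(config, dict):
        config = GeometryConfig(**config)
    cfg = config

    comps: list[Compartment] = []
    soma = Compartment(0, SOMA, cfg.soma_length, cfg.soma_diameter,
                       cfg.soma_diameter, None, 0.0, cfg.n_annuli)
    comps.append(soma)

    def add(kind, length, d1, d2, parent, branch=-1):
        pc = comps[parent]
        dist = pc.path_distance_to_soma + pc.length / 2.0 + length / 2.0
        c = Compartment(len(comps), kind, length, d1, d2, parent, dist,
                        cfg.n_annuli)
        c._branch = branch
        comps.append(c)
        return c.id

    # dendrites
    total_dend_len = cfg.comps_per_dendrite * cfg.dend_comp_length
    for b in range(cfg.n_primary_dendrites):
        parent = 0
        for j in range(cfg.comps_per_dendrite):
            if cfg.uniform_dend_diam is not None:
                d1 = d2 = cfg.uniform_dend_diam
            else:
                x0 = j * cfg.dend_comp_length / total_dend_len
                x1 = (j + 1) * cfg.dend_comp_length / total_dend_len
                span = cfg.dend_diam_proximal - cfg.dend_diam_distal
                d1 = cfg.dend_diam_proximal - span * x0
                d2 = cfg.dend_diam_proximal - span * x1
            parent = add(DENDRITE, cfg.dend_comp_length, d1, d2, parent, b)

    # axon
    if cfg.include_axon:
        ais = add(AIS, cfg.ais_length, cfg.ais_diameter, cfg.ais_diameter, 0)
        parent = ais
        for _ in range(cfg.n_internodes):
            parent = add(AXON_INTERNODE, cfg.internode_length,
                         cfg.internode_diameter, cfg.internode_diameter,
                         parent)
            parent = add(AXON_NODE, cfg.node_length, cfg.node_diameter,
                         cfg.node_diameter, parent)

    n = len(comps)
    dens = {k: np.zeros(n) for k in
            ("gbar_Na", "gbar_K", "gK_leak", "gNa_leak", "gGABA_leak")}
    syn = {"GABA_A": np.zeros(n, dtype=np.int64),
           "AMPA": np.zeros(n, dtype=np.int64)}
    for c in comps:
        dens["gbar_Na"][c.id] = DENSITY_TABLE["gbar_Na"][c.kind]
        dens["gbar_K"][c.id] = DENSITY_TABLE["gbar_Na"][c.kind] * GBAR_K_RATIO
        if c.kind == DENDRITE:
            band = _dendrite_leak_band(c.path_distance_to_soma,
                                       cfg.proximal_cutoff)
            gk, gna, gg = DENDRITE_LEAKS[band]
        else:
            gk = DENSITY_TABLE["gK_leak"][c.kind]
            gna = DENSITY_TABLE["gNa_leak"][c.kind]
            gg = DENSITY_TABLE["gGABA_leak"][c.kind]
        dens["gK_leak"][c.id] = gk
        dens["gNa_leak"][c.id] = gna
        dens["gGABA_leak"][c.id] = gg
        for key, name in (("syn_gaba_per_100um2", "GABA_A"),
                          ("syn_ampa_per_100um2", "AMPA")):
            density = DENSITY_TABLE[key][c.kind]
            if density > 0:
                cnt = int(round(density * c.membrane_area / 100.0))
                syn[name][c.id] = max(cnt, 1)

    return CellModel(comps, dens, syn, cfg.n_primary_dendrites, cfg)


def load_geometry_config(path: str | Path | None = None) -> GeometryConfig:
    """Load a geometry config from YAML (the packaged default if no path)."""
    if path is None:
        path = Path(__file__).parent / "data" / "default.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return GeometryConfig(**raw.get("geometry", {}))
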
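"""Intracellular electrodiffusion and the extracellular shell.

Longitudinal transport between axially adjacent sections follows the
Nernst-Planck flux

    J = -D (dC/dy + z C (F/RT) dV/dy)

discretized between section centers; the drift (second) term is applied
only between the *outermost* annuli, the electric field being confined to
a thin perimembrane region (the membrane acts as a capacitor and the bulk
cytosol is field free).  Radial transport between the four concentric
annuli of each compartment is pure Fickian exchange.

Because the sub-micrometre annuli of thin dendrites make radial diffusion
much stiffer than the 0.05-ms step, the radial operator is advanced with
a precomputed backward-Euler matrix per (species, compartment): the
operator is linear with constant coefficients, so ``(I - dt L)^{-1}`` is
exact, unconditionally stable, and conserves mass to machine precision.
Longitudinal exchange (section lengths >= 1 um) is integrated explicitly;
the CFL-type ratio ``D dt / dx^2`` is checked at setup.

Each compartment also owns a Frankenhaeuser-Hodgkin extracellular shell
of volume one quarter of the intracellular volume.  Shell concentrations
gain the transmembrane efflux and relax toward the infinite-bath values
with time constant ``tau_FH`` (100 ms); neighboring shells exchange by
the same Fickian operator (configurable off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (DEFAULT_CONSTANTS, DIFFUSION_1E5, SPECIES,
                        SHELL_SPECIES, VALENCE)

__all__ = [
    "DiffusionParams", "DiffusionGeometry", "build_diffusion_geometry",
    "cross_section_fractions", "radial_operator", "radial_update_matrix",
    "longitudinal_step", "radial_step", "fh_shell_step",
]

#: default bath (infinite reservoir) concentrations, mM
DEFAULT_BATH = {"Cl": 120.0, "K": 3.0, "Na": 45.0, "Ca": 2.0, "HCO3": 25.0}


@dataclass
class DiffusionParams:
    """Diffusion coefficients and extracellular-shell constants."""
    #: cm^2/s per species (order: constants.SPECIES)
    D: tuple = tuple(d * 1e-5 for d in DIFFUSION_1E5)
    tau_FH: float = 100.0            # ms
    shell_volume_ratio: float = 0.25
    bath: dict = field(default_factory=lambda: dict(DEFAULT_BATH))
    ecs_longitudinal: bool = True
    drift: bool = True

    @property
    def k_bath(self) -> np.ndarray:
        return np.array([self.bath[s] for s in SHELL_SPECIES])


def cross_section_fractions(n_annuli: int = 4) -> np.ndarray:
    """Fraction of the cross-section (= of the volume) in each
    equal-thickness ring, outermost first: (7, 5, 3, 1)/16 for n=4."""
    n = n_annuli
    out = np.empty(n)
    for i in range(n):
        ro = (n - i) / n
        ri = (n - 1 - i) / n
        out[i] = ro * ro - ri * ri
    return out


def radial_operator(radius_cm: float, length_cm: float, d_cm2_s: float,
                    n_annuli: int = 4) -> np.ndarray:
    """Rate matrix L (1/ms) of Fickian exchange between concentric annuli,
    outermost first: dC/dt = L C.  Columns conserve volume-weighted mass."""
    n = n_annuli
    r, ell = radius_cm, length_cm
    frac = cross_section_fractions(n)
    vol = math.pi * r * r * ell * frac
    L = np.zeros((n, n))
    d_ms = d_cm2_s * 1e-3
    for i in range(n - 1):
        rb = (n - 1 - i) / n * r           # interface radius
        area = 2.0 * math.pi * rb * ell
        dist = r / n                       # center-to-center
        k = d_ms * area / dist             # cm^3/ms
        L[i, i] -= k / vol[i]
        L[i, i + 1] += k / vol[i]
        L[i + 1, i + 1] -= k / vol[i + 1]
        L[i + 1, i] += k / vol[i + 1]
    return L


def radial_update_matrix(radius_cm: float, length_cm: float,
                         d_cm2_s: float, dt_ms: float,
                         n_annuli: int = 4) -> np.ndarray:
    """Backward-Euler radial propagator ``(I - dt L)^{-1}``."""
    L = radial_operator(radius_cm, length_cm, d_cm2_s, n_annuli)
    return np.linalg.inv(np.eye(n_annuli) - dt_ms * L)


@dataclass
class DiffusionGeometry:
    """Precomputed geometric factors for one cell (all lengths in cm)."""
    parent: np.ndarray        # (nc,) int64
    vol_ann: np.ndarray       # (nc, na) cm^3
    shell_vol: np.ndarray     # (nc,) cm^3
    a_edge: np.ndarray        # (nc,) cm^2 cross-section toward parent
    dist_edge: np.ndarray     # (nc,) cm, center-to-center toward parent
    f_cross: np.ndarray       # (na,)
    rad_M: np.ndarray         # (ns, nc, na, na) backward-Euler propagators

    @property
    def n_comp(self) -> int:
        return self.parent.size


def build_diffusion_geometry(cell, dt_ms: float,
                             params: DiffusionParams | None = None
                             ) -> DiffusionGeometry:
    """Geometry factors + radial propagators for every species/compartment.

    Raises a configuration error if the explicit longitudinal operator
    would violate the stability bound D dt / dx^2 > 0.5 for any species.
    """
    if params is None:
        params = DiffusionParams()
    radius = cell.radius_cm
    length = cell.length_cm
    vol = cell.volume_cm3
    parent = cell.parent
    nc = cell.n_comp
    na = cell.compartments[0].n_annuli
    f_cross = cross_section_fractions(na)
    vol_ann = vol[:, None] * f_cross[None, :]
    shell_vol = vol * params.shell_volume_ratio

    a_edge = np.zeros(nc)
    dist_edge = np.zeros(nc)
    dmax = max(params.D)
    for c in range(1, nc):
        p = parent[c]
        a_c = math.pi * radius[c] ** 2
        a_p = math.pi * radius[p] ** 2
        a_edge[c] = min(a_c, a_p)
        dist_edge[c] = 0.5 * (length[c] + length[p])
        if dmax * 1e-3 * dt_ms / dist_edge[c] ** 2 > 0.5:
            raise ValueError(
                f"longitudinal diffusion unstable for edge {c}->{p}: "
                f"D*dt/dx^2 = {dmax * 1e-3 * dt_ms / dist_edge[c] ** 2:.2f}")

    ns = len(SPECIES)
    rad_M = np.empty((ns, nc, na, na))
    for s in range(ns):
        for c in range(nc):
            rad_M[s, c] = radial_update_matrix(radius[c], length[c],
                                               params.D[s], dt_ms, na)
    return DiffusionGeometry(parent.astype(np.int64), vol_ann, shell_vol,
                             a_edge, dist_edge, f_cross, rad_M)


# ---------------------------------------------------------------------------
# reference (numpy) operators -- the integration kernel inlines the same
# arithmetic; these are the testable single-species building blocks.
# ---------------------------------------------------------------------------

def longitudinal_step(conc: np.ndarray, v: np.ndarray, dt_ms: float,
                      geom: DiffusionGeometry, d_cm2_s: float,
                      z: float = -1.0, drift: bool = True,
                      constants=DEFAULT_CONSTANTS) -> np.ndarray:
    """One explicit longitudinal electrodiffusion step for one species.

    ``conc`` has shape (nc, na) in mM (annulus 0 outermost), ``v`` (nc,)
    in mV.  Fickian flux acts on every annulus; the drift term only
    between outer annuli.  Mass is exchanged, never created.
    """
    conc = np.array(conc, dtype=float)
    na = conc.shape[1]
    rtf = constants.RT_over_F
    d_ms = d_cm2_s * 1e-3
    dq = np.zeros_like(conc)
    for c in range(1, geom.n_comp):
        p = geom.parent[c]
        base = d_ms * geom.a_edge[c] / geom.dist_edge[c]
        for a in range(na):
            grad = conc[p, a] - conc[c, a]
            if drift and a == 0:
                cbar = 0.5 * (conc[p, a] + conc[c, a])
                grad += z * cbar * (v[p] - v[c]) / rtf
            q = base * geom.f_cross[a] * grad * dt_ms    # mM*cm^3
            dq[c, a] += q / geom.vol_ann[c, a]
            dq[p, a] -= q / geom.vol_ann[p, a]
    return conc + dq


def radial_step(conc: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Backward-Euler radial exchange: conc (na,) or (nc, na) -> M @ conc."""
    conc = np.asarray(conc, dtype=float)
    if conc.ndim == 1:
        return M @ conc
    return np.einsum("ij,cj->ci", M, conc)


def fh_shell_step(shell_conc: np.ndarray, efflux_mM_per_ms: np.ndarray,
                  dt_ms: float, k_bath: np.ndarray,
                  tau_fh: float = 100.0) -> np.ndarray:
    """Forward-Euler shell update:
    d[x]_o/dt = efflux/Vol_shell + (k_bath - [x]_o)/tau_FH,
    with ``efflux_mM_per_ms`` already divided by the shell volume."""
    shell_conc = np.asarray(shell_conc, dtype=float)
    return shell_conc + dt_ms * (efflux_mM_per_ms
                                 + (k_bath - shell_conc) / tau_fh)
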
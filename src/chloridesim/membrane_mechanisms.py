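"""Transmembrane channel currents and synaptic drive.

Hodgkin-Huxley spike channels (Traub-Miles rate functions with a
threshold shift ``V_T`` and an extra slow-inactivation shift ``V_S``),
K+/Na+ leaks, a tonic GABA_A leak, optional Ca2+-activated K+ (spike
adaptation) and persistent Na+ channels, and synaptic conductances driven
by seeded Poisson processes.

Synapses have instantaneous rise and exponential decay; all synapses of
one kind on one compartment share a single decaying conductance state
(a sum of equal-tau exponentials is itself exponential).  GABA_A
conductance is carried 4:1 by Cl- and HCO3-, each against its own Nernst
potential, so the composite current reverses at the GHK ``E_GABA``.
AMPA conductance is split between Na+ and K+ with a ratio chosen so the
composite reversal sits at 0 mV for the default ionic gradients.

Current sign convention: positive = outward.  Conductance inputs in nS,
currents returned in nA (``i = g_nS * (V - E) * 1e-3`` gives nA... here we
keep nS * mV = pA * 1e3; see function docstrings for exact units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

__all__ = [
    "HHParams", "LeakParams", "AdaptationParams", "SynapsePopulation",
    "hh_step", "adaptation_currents", "sample_synaptic_events",
    "synaptic_currents", "ampa_carrier_split",
    "events_to_text", "events_from_text",
]


# ---------------------------------------------------------------------------
# Hodgkin-Huxley channels
# ---------------------------------------------------------------------------

@dataclass
class HHParams:
    """Spike-channel parameters.

    ``V_T`` shifts the rate functions to set threshold; ``V_S`` is an
    additional shift applied to inactivation only.  Densities in mS/cm^2.
    """
    gbar_Na: float = 1.2
    gbar_K: float = 1.0
    V_T: float = -58.0
    V_S: float = -10.0


@dataclass
class LeakParams:
    """Ohmic leak densities (mS/cm^2) for one compartment."""
    gK_leak: float = 0.02
    gNa_leak: float = 0.004
    gGABA_leak: float = 0.0


@njit(cache=True)
def _vtrap(x: float, k: float) -> float:
    """x / (exp(x/k) - 1) with the removable singularity at x = 0."""
    if abs(x / k) < 1e-6:
        return k * (1.0 - x / (2.0 * k))
    return x / (math.exp(x / k) - 1.0)


@njit(cache=True)
def hh_rates(v: float, v_t: float, v_s: float):
    """Traub-Miles alpha/beta (1/ms) for m, h, n at potential v (mV).

    Activation (m) and delayed rectifier (n) use v - v_t; inactivation (h)
    uses v - v_t - v_s.
    """
    u = v - v_t
    # V_S (= -10 mV) shifts the inactivation curve 10 mV toward
    # depolarization relative to activation.  The source prints only the
    # constants, not the sign convention; the opposite reading
    # (u - v_s, inactivation shifted hyperpolarized) puts the model in
    # depolarization block after a single spike at every tested drive,
    # incompatible with its documented repetitive firing.
    uh = v - v_t + v_s
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * math.exp((17.0 - uh) / 18.0)
    bh = 4.0 / (1.0 + math.exp((40.0 - uh) / 5.0))
    an = 0.032 * _vtrap(15.0 - u, 5.0)
    bn = 0.5 * math.exp((10.0 - u) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def _clamp01(x: float) -> float:
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


def hh_steady_state(v: float, params: HHParams = HHParams()):
    """(m_inf, h_inf, n_inf) at potential v."""
    am, bm, ah, bh, an, bn = hh_rates(v, params.V_T, params.V_S)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_step(v: float, gates: tuple[float, float, float], dt: float,
            params: HHParams = HHParams(),
            e_na: float = 40.1, e_k: float = -102.6):
    """One forward-Euler update of the HH gates plus the resulting currents.

    Returns ``((m, h, n), I_Na, I_K)`` with currents in mA/cm^2 (density
    form, positive outward).  Gates are clamped to [0, 1] after the update.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m, h, n = gates
    am, bm, ah, bh, an, bn = hh_rates(v, params.V_T, params.V_S)
    m = _clamp01(m + dt * (am * (1.0 - m) - bm * m))
    h = _clamp01(h + dt * (ah * (1.0 - h) - bh * h))
    n = _clamp01(n + dt * (an * (1.0 - n) - bn * n))
    i_na = params.gbar_Na * m ** 3 * h * (v - e_na) * 1e-3   # mA/cm^2
    i_k = params.gbar_K * n ** 4 * (v - e_k) * 1e-3
    return (m, h, n), i_na, i_k


# ---------------------------------------------------------------------------
# Adaptation / persistent channels (optional, off by default)
# ---------------------------------------------------------------------------

@dataclass
class AdaptationParams:
    """Ca2+-activated K+ (AHP) and persistent Na+ channel constants.

    The printed constants parameterize sigmoid activation/inactivation and
    bi-exponential time constants.  NOTE: the source equations for these
    optional channels could not be transcribed verbatim (only their
    constants are printed); the functional forms below are the standard
    sigmoid/shifted-HH readings of those constants and are flagged as a
    reconstruction.  Both channels default to zero conductance.
    """
    # AHP m gate
    c_vm: float = 28.9     # mV
    c_km: float = 6.2      # mV
    c_tm: float = 0.505    # ms (printed 0.000505 s)
    c_vtm1: float = 86.4
    c_ktm1: float = -10.1
    c_vtm2: float = -33.3
    c_ktm2: float = 10.0
    tau_z: float = 1000.0  # ms (printed 1 s)
    # AHP h gate
    c_h: float = 0.085
    c_vh: float = 32.0
    c_kh: float = -5.8
    c_th: float = 1.9      # ms (printed 0.0019 s)
    c_vth1: float = 48.5
    c_kth1: float = -54.2
    c_vth2: float = -54.2
    c_kth2: float = 12.9
    # persistent Na+ shifts
    v_sm: float = -2.0
    v_sh: float = -5.0
    gbar_AHP: float = 0.0  # mS/cm^2
    gbar_NaP: float = 0.0


@njit(cache=True)
def ahp_gate_derivs(v, m, z, c_vm, c_km, c_tm, c_vtm1, c_ktm1, c_vtm2,
                    c_ktm2, tau_z):
    """Gate derivatives (1/ms) of the adaptation (AHP) channel.

    Reconstructed form (see AdaptationParams): a fast activation gate m
    with sigmoid steady state 1/(1+exp(-(V+c_vm)/c_km)) and
    bi-exponential voltage-dependent time constant, plus a slow,
    non-inactivating gate z that integrates m with tau_z (1 s) -- the
    proxy for cumulative Ca2+ entry during sustained firing.
    """
    m_inf = 1.0 / (1.0 + math.exp(-(v + c_vm) / c_km))
    tau_m = c_tm / (math.exp((v + c_vtm1) / c_ktm1)
                    + math.exp((v + c_vtm2) / c_ktm2))
    if tau_m < 0.05:
        tau_m = 0.05
    dm = (m_inf - m) / tau_m
    dz = (m - z) / tau_z
    return dm, dz


@njit(cache=True)
def nap_gate_derivs(v, m, h, v_sm, v_sh):
    """Persistent Na+ channel gates (1/ms): standard low-threshold
    sigmoid activation (half -52 mV shifted by v_sm, slope 4.6) and a
    very slow inactivation (half -49 mV shifted by v_sh, slope 10,
    tau 2 s).  Flagged reconstruction: the source prints only the shift
    constants v_sm, v_sh.
    """
    m_inf = 1.0 / (1.0 + math.exp(-(v - (-52.0 + v_sm)) / 4.6))
    h_inf = 1.0 / (1.0 + math.exp((v - (-49.0 + v_sh)) / 10.0))
    dm = (m_inf - m) / 1.0
    dh = (h_inf - h) / 2000.0
    return dm, dh


def adaptation_currents(v: float, gates, dt: float,
                        params: AdaptationParams = AdaptationParams(),
                        e_na: float = 40.1, e_k: float = -102.6):
    """Forward-Euler update of the optional-channel gates plus currents.

    ``gates`` is (m_ahp, z_ahp, m_nap, h_nap).  Returns
    ``(gates, I_AHP, I_NaP)`` in mA/cm^2 with I_AHP = g m z (V - E_K)
    and I_NaP = g m h (V - E_Na).  With zero conductances the currents
    are identically zero.
    """
    m, z, mp, hp = gates
    dm, dz = ahp_gate_derivs(v, m, z, params.c_vm, params.c_km,
                             params.c_tm, params.c_vtm1, params.c_ktm1,
                             params.c_vtm2, params.c_ktm2, params.tau_z)
    m = _clamp01(m + dt * dm)
    z = _clamp01(z + dt * dz)
    dmp, dhp = nap_gate_derivs(v, mp, hp, params.v_sm, params.v_sh)
    mp = _clamp01(mp + dt * dmp)
    hp = _clamp01(hp + dt * dhp)
    i_ahp = params.gbar_AHP * m * z * (v - e_k) * 1e-3
    i_nap = params.gbar_NaP * mp * hp * (v - e_na) * 1e-3
    return (m, z, mp, hp), i_ahp, i_nap


# ---------------------------------------------------------------------------
# Synapses
# ---------------------------------------------------------------------------

@dataclass
class SynapsePopulation:
    """All synapses of one kind on one compartment, lumped.

    ``mean_rate`` is the Poisson rate per synapse (Hz); the population
    event rate is ``count * mean_rate``.  Per-event peak conductances are
    drawn from N(gmax_mean, gmax_sd) truncated at > 0 (resampled).
    """
    compartment_id: int
    kind: str                  # "GABA_A" | "AMPA"
    count: int
    mean_rate: float           # Hz per synapse
    gmax_mean: float = 1.0     # nS
    gmax_sd: float = 0.3       # nS
    tau_decay: float = 30.0    # ms
    g: float = 0.0             # active conductance state, nS

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("synapse count must be >= 0")
        if self.mean_rate < 0:
            raise ValueError("mean rate must be >= 0")
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be > 0")


def sample_synaptic_events(population: SynapsePopulation, t0: float,
                           t1: float, rng_seed: int):
    """Homogeneous Poisson event train for one population.

    Returns ``(times_ms, gmax_nS)`` sorted by time; identical seeds give
    identical event lists.  The synapse index within the population is
    immaterial because the population shares one conductance state.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    rate_per_ms = population.count * population.mean_rate * 1e-3
    rng = np.random.default_rng(rng_seed)
    n = rng.poisson(rate_per_ms * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, n))
    g = rng.normal(population.gmax_mean, population.gmax_sd, n)
    bad = g <= 0
    while np.any(bad):
        g[bad] = rng.normal(population.gmax_mean, population.gmax_sd,
                            int(bad.sum()))
        bad = g <= 0
    return times, g


def periodic_events(rate_hz: float, t0: float, t1: float,
                    gmax: float, phase_ms: float = 0.0):
    """Deterministic periodic train (test-synapse activation)."""
    if rate_hz <= 0:
        return np.empty(0), np.empty(0)
    period = 1e3 / rate_hz
    times = np.arange(t0 + phase_ms, t1, period)
    return times, np.full(times.size, gmax)


def ampa_carrier_split(e_na: float, e_k: float, e_rev: float = 0.0) -> float:
    """Fraction of AMPA conductance assigned to Na+ so that the composite
    Na+/K+ current reverses at ``e_rev`` (0 mV by default)."""
    # f*(e_rev - e_na) + (1-f)*(e_rev - e_k) = 0
    return (e_rev - e_k) / (e_na - e_k)


def synaptic_currents(v: float, g_gaba: float, g_ampa: float,
                      e_cl: float, e_hco3: float,
                      e_na: float = 40.1, e_k: float = -102.6,
                      dt: float = 0.0, tau_gaba: float = 30.0,
                      tau_ampa: float = 10.0,
                      hco3_frac: float = 0.2,
                      ampa_frac_na: Optional[float] = None):
    """Per-ion synaptic currents and (optionally) decayed conductances.

    Conductances in nS; currents returned in nA, positive outward:
    ``(i_ampa_na, i_ampa_k, i_gaba_cl, i_gaba_hco3, g_gaba', g_ampa')``.
    The GABA_A conductance splits (1 - hco3_frac):hco3_frac between Cl-
    and HCO3- (the 4:1 permeability ratio), each driven by its own Nernst
    potential; the composite therefore reverses exactly at the GHK E_GABA.
    If ``dt`` > 0 the conductances are decayed by exp(-dt/tau).
    """
    if ampa_frac_na is None:
        ampa_frac_na = ampa_carrier_split(e_na, e_k)
    nS_mV_to_nA = 1e-3  # nS*mV = pA
    i_gaba_cl = (1.0 - hco3_frac) * g_gaba * (v - e_cl) * nS_mV_to_nA
    i_gaba_hco3 = hco3_frac * g_gaba * (v - e_hco3) * nS_mV_to_nA
    i_ampa_na = ampa_frac_na * g_ampa * (v - e_na) * nS_mV_to_nA
    i_ampa_k = (1.0 - ampa_frac_na) * g_ampa * (v - e_k) * nS_mV_to_nA
    if dt > 0:
        g_gaba = g_gaba * math.exp(-dt / tau_gaba)
        g_ampa = g_ampa * math.exp(-dt / tau_ampa)
    return i_ampa_na, i_ampa_k, i_gaba_cl, i_gaba_hco3, g_gaba, g_ampa


# ---------------------------------------------------------------------------
# event-list text round trip (protocol replay)
# ---------------------------------------------------------------------------

def events_to_text(path, times_ms, compartments, kinds, gmax_nS):
    """Write an event list as delimited text (time_ms,compartment,kind,gmax_nS)."""
    with open(path, "w") as fh:
        fh.write("time_ms,compartment,kind,gmax_nS\n")
        for t, c, k, g in zip(times_ms, compartments, kinds, gmax_nS):
            fh.write(f"{float(t)!r},{int(c)},{k},{float(g)!r}\n")


def events_from_text(path):
    """Inverse of :func:`events_to_text`; bit-exact for float reprs."""
    times, comps, kinds, gs = [], [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            t, c, k, g = line.rstrip("\n").split(",")
            times.append(float(t)); comps.append(int(c))
            kinds.append(k); gs.append(float(g))
    return (np.array(times), np.array(comps, dtype=np.int64), kinds,
            np.array(gs))
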
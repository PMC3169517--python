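"""Executable protocols reproducing the model's in-silico experiments.

Each protocol builds its cell and configuration, runs seeded simulations,
and returns tidy pandas DataFrames plus scalar summaries.  Durations
default to scaled-down values that reach the quasi-steady regime of each
measurement on a single CPU (the full-length study conditions are 200-s
runs; see docs/methods.md for the scaling rationale).  Every protocol is
seed-reproducible and carries its configuration in the returned objects.

Summary conventions (fixed across protocols):

* steady-state window: trailing 25% of the run;
* firing rate: positive-going crossings of -10 mV with a 2-ms merge;
* "outward charge" at a synapse: time-mean of its population current,
  positive outward;
* optimal frequency: grid argmax refined by a quadratic fit through the
  argmax and its two neighbors.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .constants import ICL, IK, IHCO3
from .model_core import (GeometryConfig, build_cell, CellModel, DENDRITE,
                         AIS, SOMA)
from .engine import (SimConfig, TestSynapse, run, measure_steady_state,
                     relax_to_rest)

__all__ = [
    "protocol_kcc2_sweep", "protocol_focal_gradient",
    "protocol_somatodendritic_gradient", "protocol_ais_nkcc1",
    "protocol_kcc2_placement", "protocol_ipsc_train",
    "protocol_optimal_inhibition", "protocol_hco3_tradeoff",
    "protocol_potassium_coupling", "protocol_spiking_feedback",
    "long_dendrite_cell", "fine_grid_cell",
]

TRAIL = 0.25   # trailing fraction used for steady-state summaries


def _trailing_mean(rec, series):
    window = (rec.t[-1] - rec.t[0]) * TRAIL
    return measure_steady_state(rec, series, window)[0]


def long_dendrite_cell(n_comp: int = 60, comp_len_um: float = 5.0,
                       diam_um: float = 1.0) -> CellModel:
    """Single lengthened, uniform-diameter dendrite (the geometry used for
    focal-input and train protocols, where fine spatial resolution along
    one dendrite matters)."""
    cfg = GeometryConfig(n_primary_dendrites=1, comps_per_dendrite=n_comp,
                         dend_comp_length=comp_len_um,
                         uniform_dend_diam=diam_um)
    return build_cell(cfg)


def fine_grid_cell(n_sections: int = 40) -> CellModel:
    """One dendrite split into 1-um sections (subcompartmental KCC2
    placement protocol); no axon, to keep the model minimal."""
    cfg = GeometryConfig(n_primary_dendrites=1, comps_per_dendrite=n_sections,
                         dend_comp_length=1.0, uniform_dend_diam=1.0,
                         include_axon=False)
    return build_cell(cfg)


# ---------------------------------------------------------------------------
# background-input steady states
# ---------------------------------------------------------------------------

def protocol_kcc2_sweep(kcc2_scales=(0.1, 0.33, 1.0, 4.0),
                        f_inh_values=(0.2, 5.0), f_ratio: float = 4.0,
                        duration_ms: float = 60000.0, seeds=(0, 1, 2),
                        tonic_gaba: bool = False, cell=None,
                        record_interval: float = 50.0) -> pd.DataFrame:
    """Steady-state somatic E_Cl / E_GABA across KCC2 activity and
    background inhibitory rate (excitation at f_inh / f_ratio)."""
    if cell is None:
        cell = build_cell()
    rows = []
    for scale in kcc2_scales:
        for f_inh in f_inh_values:
            for seed in seeds:
                cfg = SimConfig(duration=duration_ms, seed=seed,
                                f_inh=f_inh, f_exc=f_inh / f_ratio,
                                kcc2_scale=scale, tonic_gaba=tonic_gaba,
                                record_interval=record_interval)
                rec = run(cfg, cell)
                rows.append(dict(
                    kcc2=scale, f_inh=f_inh, seed=seed,
                    e_cl=_trailing_mean(rec, rec.e_cl(0)),
                    e_gaba=_trailing_mean(rec, rec.e_gaba(0)),
                    e_k=_trailing_mean(rec, rec.e_k(0)),
                    mean_v=_trailing_mean(rec, rec.V[:, 0]),
                    rate_hz=rec.spikes[0] / (duration_ms * 1e-3)))
    return pd.DataFrame(rows)


def delta_ecl(df: pd.DataFrame, kcc2: float, f_lo: float = 0.2,
              f_hi: float = 5.0) -> float:
    """Depolarizing E_Cl shift between two background rates at one KCC2
    level, seed-averaged."""
    d = df[df.kcc2 == kcc2]
    return float(d[d.f_inh == f_hi].e_cl.mean()
                 - d[d.f_inh == f_lo].e_cl.mean())


# ---------------------------------------------------------------------------
# focal high-frequency input (longitudinal gradients)
# ---------------------------------------------------------------------------

def protocol_focal_gradient(distance_um: float = 200.0,
                            rate_hz: float = 50.0,
                            duration_ms: float = 3000.0,
                            kcc2_scale: float = 1.0,
                            gmax_nS: float = 1.0,
                            cell=None, extent_frac: float = 0.10):
    """Single GABA_A synapse driven periodically at high frequency on a
    lengthened dendrite; returns the spatial [Cl-]i profile, its peak
    gradient and extent, and the perisynaptic E_GABA shift at 200 ms.

    Summary keys: ``gradient_uM_per_um`` (peak spatial slope of the
    steady profile along the synapse's dendrite), ``extent_um`` (mean
    distance per side at which the [Cl-]i elevation has decayed to
    ``extent_frac`` of its peak -- "back to baseline" operationalized as
    10% of peak) and ``d_egaba_200ms_mV``.
    """
    if cell is None:
        cell = long_dendrite_cell()
    syn_comp = cell.compartment_at_distance(distance_um)
    cfg = SimConfig(duration=duration_ms, record_interval=10.0,
                    kcc2_scale=kcc2_scale, init="rest",
                    test_synapses=[TestSynapse(syn_comp, rate_hz,
                                               gmax_nS=gmax_nS)])
    rec = run(cfg, cell)
    branch = getattr(cell.compartments[syn_comp], "_branch", 0)
    dend = np.array([c.id for c in cell.compartments
                     if c.kind == DENDRITE
                     and getattr(c, "_branch", -1) == branch])
    x = cell.path_distance_um[dend]
    cl0 = rec.Cl_mean[0, dend]
    cl = rec.Cl_mean[-1, dend]
    # peak spatial gradient (uM per um) between section centers
    slope = np.abs(np.diff(cl) / np.diff(x)) * 1e3
    # spatial extent of the elevation on each side of the synapse
    elev = cl - cl0
    peak = elev.max()
    xs = cell.path_distance_um[syn_comp]
    extents = []
    for side in (x < xs, x > xs):
        xi, ei = x[side], elev[side]
        if xi.size < 3:        # synapse at a sealed end: no such side
            continue
        order = np.argsort(np.abs(xi - xs))
        dist = None
        for idx in order:
            if ei[idx] < extent_frac * peak:
                dist = abs(xi[idx] - xs)
                break
        extents.append(dist if dist is not None
                       else float(np.abs(xi - xs).max()))
    # E_GABA shift within 200 ms of onset
    i200 = np.searchsorted(rec.t, 200.0)
    egaba = rec.e_gaba(syn_comp)
    e0 = rec.config.constants.RT_over_F * math.log(
        (4 * rec.Ci_out[0, ICL, syn_comp] + rec.Ci_out[0, IHCO3, syn_comp])
        / (4 * rec.Co[0, ICL, syn_comp] + rec.Co[0, IHCO3, syn_comp]))
    profile = pd.DataFrame(dict(distance_um=x, cl_mM=cl, cl_initial_mM=cl0,
                                elevation_mM=elev))
    summary = dict(gradient_uM_per_um=float(slope.max()),
                   extent_um=float(np.mean(extents)),
                   d_egaba_200ms_mV=float(egaba[i200] - e0),
                   syn_comp=syn_comp, peak_cl_mM=float(cl.max()))
    return profile, summary, rec


def protocol_focal_interaction(separations_um=(10, 25, 50, 100),
                               kcc2_scales=(1.0, 0.1),
                               same_dendrite: bool = True,
                               duration_ms: float = 2000.0,
                               cell=None) -> pd.DataFrame:
    """Fifty-Hz conditioning synapse plus a 5-Hz test synapse at varying
    separation, on the same or a different primary dendrite; returns the
    test-synapse E_GABA shift."""
    rows = []
    for scale in kcc2_scales:
        for sep in separations_um:
            c = cell
            if c is None:
                c = build_cell(GeometryConfig(
                    n_primary_dendrites=2, comps_per_dendrite=20,
                    dend_comp_length=10.0, uniform_dend_diam=1.0))
            cond = c.compartment_at_distance(100.0, dendrite=0)
            test = c.compartment_at_distance(
                100.0 + sep if same_dendrite else sep,
                dendrite=0 if same_dendrite else 1)
            cfg = SimConfig(duration=duration_ms, kcc2_scale=scale,
                            init="rest",
                            test_synapses=[TestSynapse(cond, 50.0),
                                           TestSynapse(test, 5.0)])
            rec = run(cfg, c)
            eg = rec.e_gaba(test)
            cl = rec.Ci_out[:, ICL, test]
            rows.append(dict(kcc2=scale, separation_um=sep,
                             same_dendrite=same_dendrite,
                             d_cl_mM=float(cl[-1] - cl[0]),
                             d_egaba=float(eg[-1] - eg[0])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# somato-dendritic standing gradient
# ---------------------------------------------------------------------------

def protocol_somatodendritic_gradient(f_inh: float = 0.8,
                                      f_exc: float = 0.2,
                                      duration_ms: float = 20000.0,
                                      seed: int = 0,
                                      cell=None) -> pd.DataFrame:
    """[Cl-]i vs distance from soma for the four combinations of
    background noise x uniform KCC2; the standing gradient requires both."""
    if cell is None:
        cell = build_cell()
    dend = cell.dendritic_ids()[:10]     # one primary dendrite
    # every arm starts from the same KCC2-on resting state; "no KCC2"
    # means extrusion removed at t = 0, the experimental manipulation
    rest = relax_to_rest(cell, config=SimConfig(kcc2_scale=1.0))
    rows = []
    for noise in (True, False):
        for kcc2 in (True, False):
            cfg = SimConfig(duration=duration_ms, seed=seed,
                            f_inh=f_inh if noise else 0.0,
                            f_exc=f_exc if noise else 0.0,
                            kcc2_scale=1.0 if kcc2 else 0.0,
                            init=rest, record_interval=50.0)
            rec = run(cfg, cell)
            n = rec.Cl_mean.shape[0]
            tail = rec.Cl_mean[int(n * (1 - TRAIL)):, :].mean(axis=0)
            for c in np.concatenate(([0], dend)):
                rows.append(dict(noise=noise, kcc2=kcc2,
                                 distance_um=cell.path_distance_um[c],
                                 cl_mM=float(tail[c])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AIS NKCC1 and subcompartmental KCC2 placement
# ---------------------------------------------------------------------------

def protocol_ais_nkcc1(nkcc1_levels=(0.0, 1.0), kcc2_levels=(1.0, 0.33),
                       noise: bool = False, duration_ms: float = 20000.0,
                       seed: int = 0, cell=None) -> pd.DataFrame:
    """Axo-somato-dendritic [Cl-]i profile with NKCC1 confined to the AIS
    and KCC2 excluded from it (signed distance: axon negative)."""
    if cell is None:
        cell = build_cell()
    kind = cell.kind
    dend = cell.dendritic_ids()[:10]
    ais = int(np.where(kind == AIS)[0][0])
    rows = []
    for nk in nkcc1_levels:
        for kc in kcc2_levels:
            cfg = SimConfig(duration=duration_ms, seed=seed,
                            f_inh=0.4 if noise else 0.0,
                            f_exc=0.1 if noise else 0.0,
                            kcc2_scale=kc, kcc2_in_ais=False,
                            nkcc1_scale=nk, init="rest",
                            record_interval=100.0)
            rec = run(cfg, cell)
            n = rec.Cl_mean.shape[0]
            tail = rec.Cl_mean[int(n * (1 - TRAIL)):, :].mean(axis=0)
            for c in np.concatenate(([ais], [0], dend)):
                d = cell.path_distance_um[c]
                rows.append(dict(
                    nkcc1=nk, kcc2=kc, noise=noise,
                    distance_um=-d if kind[c] in (AIS,) else d,
                    kind=int(kind[c]), cl_mM=float(tail[c])))
    return pd.DataFrame(rows)


def protocol_kcc2_placement(positions=(1, 5, 10, 15, 19),
                            rate_hz: float = 50.0,
                            duration_ms: float = 8000.0,
                            cell=None):
    """Concentrate each 20-um block's entire KCC2 at a single 1-um section
    at varying distance from a high-frequency synapse (total KCC2 per
    block constant); returns perisynaptic steady E_Cl per placement and
    the max-minus-min spread.

    The fine-grid dendrite has 40 one-um sections; synapses sit 20 um
    apart at 10 um and 30 um.  Placement p puts all KCC2 of block
    [0,20) at section p and of block [20,40) at section 20+p.
    """
    if cell is None:
        cell = fine_grid_cell(40)
    dend = cell.dendritic_ids()
    syn_a = cell.compartment_at_distance(10.0)
    syn_b = cell.compartment_at_distance(30.0)
    rows = []
    for p in positions:
        scale = np.zeros(cell.n_comp)
        scale[0] = 1.0                       # soma keeps its normal KCC2
        scale[dend[p]] = 20.0                # block 1 concentrated
        scale[dend[20 + p]] = 20.0           # block 2 concentrated
        cfg = SimConfig(duration=duration_ms, kcc2_scale=scale,
                        record_interval=20.0, init="rest",
                        test_synapses=[TestSynapse(syn_a, rate_hz),
                                       TestSynapse(syn_b, rate_hz)])
        rec = run(cfg, cell)
        ecl = rec.e_cl(syn_a)
        rows.append(dict(position_um=p, e_cl=_trailing_mean(rec, ecl)))
    df = pd.DataFrame(rows)
    spread = float(df.e_cl.max() - df.e_cl.min())
    return df, spread


# ---------------------------------------------------------------------------
# IPSC trains
# ---------------------------------------------------------------------------

def protocol_ipsc_train(sites_um=(0.0, 40.0, 100.0, 240.0),
                        kcc2_scales=(1.0, 0.0), rate_hz: float = 40.0,
                        duration_ms: float = 10000.0,
                        background: bool = False, seed: int = 0,
                        cell=None) -> pd.DataFrame:
    """40-Hz IPSC trains (200 ms bursts every second) at sites from soma
    to distal dendrite; reports early and late intraburst mean IPSC (uA,
    outward positive) and the burst-end E_Cl shift."""
    if cell is None:
        cell = long_dendrite_cell()
    rest = relax_to_rest(cell, config=SimConfig(kcc2_scale=1.0))
    rows = []
    for site in sites_um:
        comp = 0 if site == 0 else cell.compartment_at_distance(site)
        for kc in kcc2_scales:
            cfg = SimConfig(duration=duration_ms, seed=seed,
                            kcc2_scale=kc, record_interval=5.0,
                            init="nominal" if background else rest,
                            f_inh=0.4 if background else 0.0,
                            f_exc=0.1 if background else 0.0,
                            test_synapses=[TestSynapse(
                                comp, rate_hz, burst_ms=200.0,
                                burst_period_ms=1000.0)])
            rec = run(cfg, cell)
            pop = len(rec.pop_label) - 1          # test synapse is last
            i_test = rec.pop_current[:, pop]
            phase = rec.t % 1000.0
            burst = phase < 200.0
            n = rec.t.size
            first = burst & (rec.t < 1000.0)
            late = burst & (rec.t > duration_ms * (1 - TRAIL))
            ecl = rec.e_cl(comp)
            rows.append(dict(
                site_um=site, kcc2=kc, background=background,
                ipsc_first_uA=float(i_test[first].mean()),
                ipsc_late_uA=float(i_test[late].mean()),
                d_ecl_mV=float(_trailing_mean(rec, ecl) - ecl[0]),
                inverted=bool(i_test[late].mean() < 0.0)))
    return pd.DataFrame(rows)


def protocol_held_open_convergence(sites_um=(40.0, 100.0, 240.0),
                                   kcc2_scales=(1.0, 0.33),
                                   g_nS: float = 1.0,
                                   duration_ms: float = 12000.0,
                                   cell=None) -> pd.DataFrame:
    """Hold GABA_A receptors open at a site and fit the E_Cl convergence
    with a single exponential (steady level and time constant per site
    and KCC2 level); fit failures are flagged rather than raised."""
    from scipy.optimize import curve_fit
    if cell is None:
        cell = long_dendrite_cell()
    rows = []
    for site in sites_um:
        comp = cell.compartment_at_distance(site)
        for kc in kcc2_scales:
            cfg = SimConfig(duration=duration_ms, kcc2_scale=kc,
                            record_interval=10.0, init="rest",
                            gaba_windows=[(comp, g_nS, 0.0, duration_ms)])
            rec = run(cfg, cell)
            ecl = rec.e_cl(comp)
            t = rec.t * 1e-3
            ok, e_ss, tau = True, float(ecl[-1]), float("nan")
            try:
                popt, _ = curve_fit(
                    lambda tt, a, b, c: a + b * np.exp(-tt / c),
                    t, ecl, p0=(ecl[-1], ecl[0] - ecl[-1], 1.0),
                    maxfev=5000)
                e_ss, tau = float(popt[0]), float(popt[2])
            except Exception:
                ok = False
            rows.append(dict(site_um=site, kcc2=kc, e_cl_ss=e_ss,
                             tau_s=tau, fit_ok=ok))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optimal inhibition
# ---------------------------------------------------------------------------

def protocol_optimal_inhibition(freqs, kcc2_scale: float = 1.0,
                                tau_ipsc: float = 10.0,
                                duration_ms: float = 12000.0,
                                discard_ms: float = 2000.0,
                                site_um: float = 50.0,
                                f_inh: float = 0.4, f_exc: float = 0.1,
                                seed: int = 0, cell=None):
    """Sweep the activation rate of one dendritic test synapse and find
    the frequency maximizing its mean outward charge transfer.

    Returns ``(DataFrame, f_opt)`` where f_opt refines the grid argmax
    with a quadratic through its neighbors.
    """
    if cell is None:
        cell = build_cell()
    comp = cell.compartment_at_distance(site_um)
    rows = []
    for f in freqs:
        cfg = SimConfig(duration=duration_ms, seed=seed,
                        f_inh=f_inh, f_exc=f_exc, kcc2_scale=kcc2_scale,
                        record_interval=5.0,
                        test_synapses=[TestSynapse(comp, float(f),
                                                   tau_ms=tau_ipsc)])
        rec = run(cfg, cell)
        pop = len(rec.pop_label) - 1
        sel = rec.t > discard_ms
        q = float(rec.pop_current[sel, pop].mean())
        rows.append(dict(freq_hz=float(f), mean_outward_uA=q))
    df = pd.DataFrame(rows)
    f_opt = refine_argmax(df.freq_hz.values, df.mean_outward_uA.values)
    return df, f_opt


def refine_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Quadratic refinement of a grid argmax (falls back to the grid
    point at the edges or for degenerate curvature)."""
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:
        return float(x1)
    # vertex of the parabola through the three points (uniform grid form)
    return float(x1 + 0.5 * (y0 - y2) / denom * (x2 - x1))


def protocol_distributed_vs_clustered(site_um: float = 200.0,
                                      duration_ms: float = 6000.0,
                                      seed: int = 0, cell=None):
    """One 50-Hz synapse vs ten distributed 5-Hz synapses (same total
    input) on distal dendrites: total outward charge of each arrangement."""
    if cell is None:
        cell = build_cell()
    # clustered: one synapse at the site
    comp = cell.compartment_at_distance(site_um)
    cfg1 = SimConfig(duration=duration_ms, seed=seed, record_interval=5.0,
                     test_synapses=[TestSynapse(comp, 50.0)])
    rec1 = run(cfg1, cell)
    # distributed: ten 5-Hz synapses spread over the distal halves
    dend = cell.dendritic_ids()
    far = [int(c) for c in dend if cell.path_distance_um[c] >= 100.0]
    comps = [far[i * len(far) // 10] for i in range(10)]
    cfg2 = SimConfig(duration=duration_ms, seed=seed, record_interval=5.0,
                     test_synapses=[TestSynapse(c, 5.0) for c in comps])
    rec2 = run(cfg2, cell)
    ntest1 = 1
    q1 = float(rec1.q_pop[-ntest1:].sum())
    q2 = float(rec2.q_pop[-10:].sum())
    return dict(clustered_charge=q1, distributed_charge=q2)


# ---------------------------------------------------------------------------
# HCO3-/Cl- trade-off
# ---------------------------------------------------------------------------

def protocol_hco3_tradeoff(variant: str = "standard",
                           g_nS: float = 1.0, site_um: float = 100.0,
                           duration_ms: float = 15000.0,
                           clhco3_scale=None,
                           acid_load_mA_cm2: float = 0.01,
                           cell=None):
    """GABA_A receptors held open on a dendrite; trajectories of E_Cl,
    E_HCO3, E_GABA and the synaptic-site current under homeostatic
    variants.

    variants: standard | no_hco3 (Cl--only receptor) | hco3_clamped |
    h_extrusion_33 | cl_clamped | kcc2_10 | exchanger (Cl-/HCO3- on) |
    acid_load (5-s imposed H+ influx, exchanger on).
    """
    if cell is None:
        cell = build_cell()
    comp = cell.compartment_at_distance(site_um)
    kw = dict(duration=duration_ms, record_interval=10.0,
              clhco3_scale=0.0 if clhco3_scale is None else clhco3_scale,
              init="rest",
              gaba_windows=[(comp, g_nS, 0.0, duration_ms)])
    if variant == "no_hco3":
        pass                      # handled below via hco3-free receptor
    elif variant == "hco3_clamped":
        kw["clamp_species"] = ("HCO3",)
    elif variant == "h_extrusion_33":
        kw["nah_scale"] = 0.33
    elif variant == "cl_clamped":
        kw["clamp_species"] = ("Cl",)
    elif variant == "kcc2_10":
        kw["kcc2_scale"] = 0.1
    elif variant == "exchanger":
        if clhco3_scale is None:
            kw["clhco3_scale"] = 1.0
    elif variant == "acid_load":
        if clhco3_scale is None:
            kw["clhco3_scale"] = 1.0
        kw["gaba_windows"] = []
        kw["acid_loads"] = [(comp, acid_load_mA_cm2, 2000.0, 7000.0)]
    elif variant != "standard":
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "no_hco3":
        # chloride-only receptor with the same Cl- conductance as standard
        kw["gaba_hco3_frac"] = 0.0
        kw["gaba_windows"] = [(comp, g_nS * 0.8, 0.0, duration_ms)]
    cfg = SimConfig(**kw)
    rec = run(cfg, cell)
    out = pd.DataFrame(dict(
        t_ms=rec.t, e_cl=rec.e_cl(comp), e_hco3=rec.e_hco3(comp),
        e_gaba=rec.e_gaba(comp), v=rec.V[:, comp],
        ph_i=rec.ph_i(comp)))
    return out, rec


# ---------------------------------------------------------------------------
# extracellular potassium coupling
# ---------------------------------------------------------------------------

def protocol_potassium_coupling(kcc2_scales=(0.1, 1.0, 4.0),
                                f_inh: float = 0.8, f_exc: float = 0.2,
                                duration_ms: float = 30000.0,
                                seed: int = 0, cell=None) -> pd.DataFrame:
    """Background-input sweep of KCC2: steady somatic E_K vs E_Cl (E_K is
    expected to move far less than E_Cl)."""
    if cell is None:
        cell = build_cell()
    rows = []
    for kc in kcc2_scales:
        cfg = SimConfig(duration=duration_ms, seed=seed, f_inh=f_inh,
                        f_exc=f_exc, kcc2_scale=kc, record_interval=50.0)
        rec = run(cfg, cell)
        rows.append(dict(kcc2=kc,
                         e_k=_trailing_mean(rec, rec.e_k(0)),
                         e_cl=_trailing_mean(rec, rec.e_cl(0)),
                         ko_peak=float(rec.Co[:, IK, :].max())))
    return pd.DataFrame(rows)


def protocol_heavy_load_ko(kcc2_scales=(0.1, 1.0, 4.0),
                           tau_fh_values=(100.0, 200.0),
                           g_nS: float = 5.0, load_ms: float = 500.0,
                           site_um: float = 100.0, cell=None) -> pd.DataFrame:
    """Peak [K+]_o under a constant GABA_A conductance load on a dendrite
    for normal and 50%-slower extracellular clearance."""
    from .electrodiffusion import DiffusionParams
    if cell is None:
        cell = build_cell()
    comp = cell.compartment_at_distance(site_um)
    rows = []
    for tau in tau_fh_values:
        for kc in kcc2_scales:
            cfg = SimConfig(duration=load_ms + 1500.0, kcc2_scale=kc,
                            record_interval=5.0, init="rest",
                            diffusion=DiffusionParams(tau_FH=tau),
                            gaba_windows=[(comp, g_nS, 500.0,
                                           500.0 + load_ms)])
            rec = run(cfg, cell)
            rows.append(dict(tau_fh=tau, kcc2=kc,
                             ko_peak=float(rec.Co[:, IK, comp].max())))
    return pd.DataFrame(rows)


def protocol_ko_clamp(ko_values=(3.0, 5.0, 7.0, 9.0, 11.0, 13.0),
                      f_inh: float = 0.8, f_exc: float = 0.2,
                      duration_ms: float = 25000.0, seed: int = 0,
                      cell=None):
    """Clamp shell [K+]_o and measure the steady somatic KCC2 Cl- flux;
    returns the DataFrame and the interpolated [K+]_o at which the flux
    crosses zero."""
    if cell is None:
        cell = build_cell()
    rows = []
    for ko in ko_values:
        cfg = SimConfig(duration=duration_ms, seed=seed, f_inh=f_inh,
                        f_exc=f_exc, clamp_shell={"K": float(ko)},
                        record_interval=50.0)
        rec = run(cfg, cell)
        rows.append(dict(
            ko=float(ko),
            kcc2_flux=_trailing_mean(rec, rec.kcc2_flux[:, 0]),
            e_cl=_trailing_mean(rec, rec.e_cl(0))))
    df = pd.DataFrame(rows)
    ko0 = zero_crossing(df.ko.values, df.kcc2_flux.values)
    return df, ko0


def zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """x at which y crosses zero (linear interpolation); if y never
    crosses, extrapolate from the last two points."""
    s = np.sign(y)
    idx = np.where(np.diff(s) != 0)[0]
    if idx.size:
        i = int(idx[0])
        return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    i = len(x) - 2
    return float(x[i] - y[i] * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))


# ---------------------------------------------------------------------------
# spiking feedback
# ---------------------------------------------------------------------------

def protocol_spiking_feedback(f_exc_values=(0.2, 0.4, 0.8, 1.6),
                              f_inh: float = 0.4,
                              duration_ms: float = 20000.0,
                              seed: int = 0, cell=None) -> pd.DataFrame:
    """E_Cl scaling with excitatory drive at fixed inhibitory rate."""
    if cell is None:
        cell = build_cell()
    rows = []
    for fe in f_exc_values:
        cfg = SimConfig(duration=duration_ms, seed=seed, f_inh=f_inh,
                        f_exc=fe, record_interval=50.0)
        rec = run(cfg, cell)
        rows.append(dict(f_exc=fe,
                         e_cl=_trailing_mean(rec, rec.e_cl(0)),
                         mean_v=_trailing_mean(rec, rec.V[:, 0]),
                         rate_hz=rec.spikes[0] / (duration_ms * 1e-3)))
    return pd.DataFrame(rows)


def protocol_spiking_vs_static(kcc2_scale: float = 0.1,
                               f_inh: float = 0.8, f_exc: float = 0.4,
                               duration_ms: float = 20000.0,
                               hh_scale: float = 30.0,
                               seed: int = 0, cell=None):
    """Steady somatic [Cl-]i with and without HH channels under identical
    input (spiking exacerbates Cl- accumulation)."""
    if cell is None:
        cell = build_cell()
    out = {}
    for hh in (True, False):
        cfg = SimConfig(duration=duration_ms, seed=seed, f_inh=f_inh,
                        f_exc=f_exc, kcc2_scale=kcc2_scale, hh=hh,
                        hh_scale=hh_scale, record_interval=50.0)
        rec = run(cfg, cell)
        out[hh] = dict(cl=_trailing_mean(rec, rec.Cl_mean[:, 0]),
                       rate_hz=rec.spikes[0] / (duration_ms * 1e-3))
    return out


def protocol_gaba_clamp_biphasic(i_nA: float = 0.3, g_nS: float = 10.0,
                                 duration_ms: float = 20000.0,
                                 hh_scale: float = 30.0, cell=None):
    """Constant somatic excitatory current, then a constant somatic
    GABA_A conductance: spiking stops, Cl- accumulates, spiking resumes
    with a second accelerated phase of accumulation."""
    if cell is None:
        cell = build_cell()
    cfg = SimConfig(duration=duration_ms, record_interval=5.0,
                    kcc2_scale=0.33, init="rest", hh_scale=hh_scale,
                    current_injections=[(0, i_nA, 1000.0, duration_ms)],
                    gaba_windows=[(0, g_nS, 5000.0, duration_ms)])
    rec = run(cfg, cell)
    return pd.DataFrame(dict(t_ms=rec.t, v=rec.V[:, 0],
                             cl=rec.Cl_mean[:, 0])), rec


def protocol_io_curves(f_exc_values=(0.2, 0.4, 0.8, 1.2, 1.6),
                       inh_ratio: float = 2.0,
                       duration_ms: float = 15000.0, seed: int = 0,
                       static_egaba: float = -65.0, hh_scale: float = 30.0,
                       kcc2_scale: float = 0.33, cell=None) -> pd.DataFrame:
    """Firing rate vs proportional excitatory+inhibitory drive for a
    conventional static-E_GABA model vs the full dynamic-chloride model."""
    if cell is None:
        cell = build_cell()
    rows = []
    for fe in f_exc_values:
        for dynamic in (True, False):
            cfg = SimConfig(
                duration=duration_ms, seed=seed, f_exc=fe,
                f_inh=inh_ratio * fe, kcc2_scale=kcc2_scale,
                hh_scale=hh_scale, record_interval=50.0,
                fix_egaba=None if dynamic else static_egaba,
                clamp_species=() if dynamic else ("Cl", "HCO3"))
            rec = run(cfg, cell)
            rows.append(dict(f_exc=fe, dynamic=dynamic,
                             rate_hz=rec.spikes[0] / (duration_ms * 1e-3)))
    return pd.DataFrame(rows)
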
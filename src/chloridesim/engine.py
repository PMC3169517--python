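"""Simulation assembly, integration driver, recording and measurement.

`SimConfig` declares everything about a run (step, duration, background
rates, mechanism scales, clamps, stimuli, seed); `Simulation` compiles it
against a `CellModel` into flat arrays and hands them to the compiled
kernel; `TimeSeriesRecord` carries the sampled traces with enough
metadata to re-run bit-identically.

Background synaptic bombardment is Poisson per synapse; all synapses of
one kind on one compartment are lumped into one population with one
counter-based RNG stream each (spawned from the run seed), so adding a
recorder or another population never perturbs existing event sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernel
from .constants import (DEFAULT_CONSTANTS, EXTRACELLULAR_PH, FARADAY,
                        SPECIES, SHELL_SPECIES, VALENCE, DIFFUSION_1E5,
                        ICL, IK, INA, ICA, IHCO3, IH, IH2PO4, IHPO4,
                        PhysicalConstants)
from .model_core import (CellModel, build_cell, SOMA, DENDRITE, AIS,
                         AXON_NODE, AXON_INTERNODE)
from .membrane_mechanisms import (AdaptationParams, SynapsePopulation,
                                  sample_synaptic_events, periodic_events,
                                  ampa_carrier_split, hh_steady_state,
                                  HHParams)
from .transport import (PumpParams, KCC2Params, NKCC1Params, ClHCO3Params,
                        calibrate_pump)
from .chemistry import ChemistryParams
from .electrodiffusion import DiffusionParams, build_diffusion_geometry

__all__ = [
    "SimConfig", "TestSynapse", "InitialState", "TimeSeriesRecord",
    "Simulation", "run", "relax_to_rest", "measure_steady_state",
    "nominal_state",
]

#: printed initial intracellular concentrations (mM); Ca2+ is inert
CI_INIT = {"Cl": 6.0, "K": 140.0, "Na": 10.0, "Ca": 1e-4,
           "HCO3": 15.0, "H": 10.0 ** -4.2, "H2PO4": 30.0, "HPO4": 30.0}


@dataclass
class TestSynapse:
    """A probed synapse population driven by its own event train."""
    compartment: int
    rate_hz: float
    kind: str = "GABA_A"         # "GABA_A" | "AMPA"
    gmax_nS: float = 1.0
    gmax_sd_nS: float = 0.0
    tau_ms: float = 30.0
    count: int = 1
    periodic: bool = True        # deterministic train; False -> Poisson
    #: single-synapse populations saturate: an event resets the
    #: conductance to its peak instead of summing (a synapse that is
    #: already open cannot open further)
    saturating: bool = True
    t_start_ms: float = 0.0
    t_stop_ms: Optional[float] = None
    burst_ms: Optional[float] = None     # on-window within each period_s
    burst_period_ms: Optional[float] = None


@dataclass
class InitialState:
    Ci: np.ndarray       # (8, nc, na) mM
    Co: np.ndarray       # (5, nc) mM
    V: np.ndarray        # (nc,) mV
    gates: np.ndarray    # (8, nc)

    def copy(self) -> "InitialState":
        return InitialState(self.Ci.copy(), self.Co.copy(), self.V.copy(),
                            self.gates.copy())


@dataclass
class SimConfig:
    """Integration and protocol settings (times in ms, rates in Hz)."""
    dt: float = 0.05
    duration: float = 1000.0
    record_interval: float = 10.0
    seed: int = 0
    # background bombardment (per-synapse Poisson rates)
    f_inh: float = 0.0
    f_exc: float = 0.0
    # mechanism scales
    kcc2_scale: Union[float, np.ndarray] = 1.0
    kcc2_in_ais: bool = True
    nkcc1_scale: float = 0.0          # AIS only
    clhco3_scale: float = 0.0         # Cl-/HCO3- exchanger, ubiquitous
    nah_scale: float = 1.0            # Na+/H+ exchanger
    tonic_gaba: bool = False
    hh: bool = True
    #: multiplier on the HH densities.  The printed densities (1.2 mS/cm^2
    #: soma/dendrites, 12 AIS) support only single spikes from rest; the
    #: cited conductance-based model family uses 10x those values
    #: (12 mS/cm^2 soma/dendrites, ~120 axon initial segment), which is
    #: what the spiking protocols use (hh_scale=10).  See docs/methods.md.
    hh_scale: float = 1.0
    ahp: bool = False                 # Ca2+-activated K+ channel
    nap: bool = False                 # persistent Na+ channel
    gbar_AHP: float = 2.0             # mS/cm^2 where HH is present
    gbar_NaP: float = 0.1
    mechanisms_enabled: bool = True   # False: freeze everything (fixed point)
    # physics switches
    drift: bool = True
    ecs_diffusion: bool = True
    chem: bool = True
    #: if True (default), the AMPA current is carried by Na+/K+ in the
    #: concentration books (mass-closed, so the pump sees the excitatory
    #: Na+ load and K+ stays balanced); False treats excitatory current
    #: as electrical-only (conventional-model variant).
    ampa_mass_flux: bool = True
    #: HCO3- share of the GABA_A conductance (4:1 Cl-:HCO3- permeability);
    #: 0 models a chloride-only receptor.
    gaba_hco3_frac: float = 0.2
    # clamps and stimuli
    clamp_species: tuple = ()                 # e.g. ("Cl",), ("HCO3",)
    clamp_shell: Optional[dict] = None        # e.g. {"K": 10.0}
    voltage_clamp: Optional[tuple] = None     # (comp, mV)
    fix_egaba: Optional[float] = None         # conventional-model mode
    test_synapses: list = field(default_factory=list)
    gaba_windows: list = field(default_factory=list)   # (comp,nS,t0,t1)
    current_injections: list = field(default_factory=list)  # (comp,nA,t0,t1)
    acid_loads: list = field(default_factory=list)     # (comp,mA/cm^2,t0,t1)
    init: Union[str, InitialState] = "nominal"
    # parameter bundles
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    pump: PumpParams = field(default_factory=PumpParams)
    kcc2: KCC2Params = field(default_factory=KCC2Params)
    nkcc1: NKCC1Params = field(default_factory=NKCC1Params)
    clhco3: ClHCO3Params = field(default_factory=ClHCO3Params)
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    hh_params: HHParams = field(default_factory=HHParams)


@dataclass
class TimeSeriesRecord:
    """Sampled traces with (quantity, compartment, annulus|shell) access."""
    t: np.ndarray                 # ms
    V: np.ndarray                 # (nt, nc)
    Ci_out: np.ndarray            # (nt, 8, nc) outer-annulus concentrations
    Cl_mean: np.ndarray           # (nt, nc) volume-weighted mean [Cl-]i
    Co: np.ndarray                # (nt, 5, nc) shell concentrations
    kcc2_flux: np.ndarray         # (nt, nc) Cl- current equivalent, uA/cm^2
    pop_current: np.ndarray       # (nt, npop) uA, positive outward
    pop_comp: np.ndarray
    pop_is_gaba: np.ndarray
    pop_label: list
    q_pop: np.ndarray             # accumulated charge per population, uA*ms
    spikes: np.ndarray            # (nc,) threshold crossings
    gate_clamps: int
    seed: int
    config: SimConfig
    cell: CellModel
    final_state: InitialState

    @property
    def rtf(self) -> float:
        return self.config.constants.RT_over_F

    def e_cl(self, comp: int) -> np.ndarray:
        return self.rtf * np.log(self.Ci_out[:, ICL, comp]
                                 / self.Co[:, ICL, comp])

    def e_k(self, comp: int) -> np.ndarray:
        return self.rtf * np.log(self.Co[:, IK, comp]
                                 / self.Ci_out[:, IK, comp])

    def e_na(self, comp: int) -> np.ndarray:
        return self.rtf * np.log(self.Co[:, INA, comp]
                                 / self.Ci_out[:, INA, comp])

    def e_hco3(self, comp: int) -> np.ndarray:
        return self.rtf * np.log(self.Ci_out[:, IHCO3, comp]
                                 / self.Co[:, IHCO3, comp])

    def e_gaba(self, comp: int, perm_ratio: float = 4.0) -> np.ndarray:
        num = perm_ratio * self.Ci_out[:, ICL, comp] \
            + self.Ci_out[:, IHCO3, comp]
        den = perm_ratio * self.Co[:, ICL, comp] + self.Co[:, IHCO3, comp]
        return self.rtf * np.log(num / den)

    def ph_i(self, comp: int) -> np.ndarray:
        return -np.log10(self.Ci_out[:, IH, comp] * 1e-3)

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path, t=self.t, V=self.V, Ci_out=self.Ci_out,
            Cl_mean=self.Cl_mean, Co=self.Co, kcc2_flux=self.kcc2_flux,
            pop_current=self.pop_current, q_pop=self.q_pop,
            spikes=self.spikes, seed=self.seed)


def measure_steady_state(record: TimeSeriesRecord, series: np.ndarray,
                         window_ms: float):
    """Mean and sd of a recorded series over the trailing window."""
    t = record.t
    if window_ms > t[-1] - t[0] + (t[1] - t[0] if t.size > 1 else 0.0):
        raise ValueError("window exceeds record length")
    sel = t > t[-1] - window_ms
    x = np.asarray(series)[sel]
    return float(np.mean(x)), float(np.std(x))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def nominal_state(cell: CellModel, config: SimConfig) -> InitialState:
    """Printed initial concentrations, shells at bath, V and gates at the
    calibrated leak/pump resting point."""
    nc = cell.n_comp
    na = cell.compartments[0].n_annuli
    Ci = np.empty((8, nc, na))
    for x, s in enumerate(SPECIES):
        Ci[x] = CI_INIT[s]
    bath = config.diffusion.bath
    Co = np.empty((5, nc))
    for x, s in enumerate(SHELL_SPECIES):
        Co[x] = bath[s]
    rtf = config.constants.RT_over_F
    e_k = rtf * math.log(bath["K"] / CI_INIT["K"])
    e_na = rtf * math.log(bath["Na"] / CI_INIT["Na"])
    v0, _ = calibrate_pump(e_k, e_na, bath["K"], CI_INIT["Na"],
                           params=config.pump, rt_over_f=rtf)
    V = np.full(nc, v0)
    gates = np.zeros((8, nc))
    m, h, n = hh_steady_state(v0, config.hh_params)
    gates[0], gates[1], gates[2] = m, h, n
    gates[6] = 1.0   # NaP inactivation starts open
    return InitialState(Ci, Co, V, gates)


class Simulation:
    """Compile a SimConfig + CellModel into kernel arrays and run."""

    def __init__(self, config: SimConfig, cell: Optional[CellModel] = None):
        self.config = config
        self.cell = cell if cell is not None else build_cell()
        self._build()

    # -- geometry and densities -------------------------------------------
    def _build(self) -> None:
        cfg = self.config
        cell = self.cell
        nc = cell.n_comp
        kind = cell.kind
        self.geom = build_diffusion_geometry(cell, cfg.dt, cfg.diffusion)
        area = cell.area_cm2
        radius = cell.radius_cm
        length = cell.length_cm
        # axial coupling conductances (mS): R_a * L/2 / cross-section
        gax = np.zeros(nc)
        ra = cfg.constants.R_a
        parent = cell.parent
        for c in range(1, nc):
            p = parent[c]
            r_half = (ra * 0.5 * length[c] / (math.pi * radius[c] ** 2)
                      + ra * 0.5 * length[p] / (math.pi * radius[p] ** 2))
            gax[c] = 1e3 / r_half
        self.gax = gax

        dens = cell.mechanism_densities
        on = 1.0 if cfg.mechanisms_enabled else 0.0
        hh_on = on if cfg.hh else 0.0
        self.gna = dens["gbar_Na"] * hh_on * cfg.hh_scale
        self.gk = dens["gbar_K"] * hh_on * cfg.hh_scale
        self.gkleak = dens["gK_leak"] * on
        self.gnaleak = dens["gNa_leak"] * on
        self.gtonic = dens["gGABA_leak"] * (on if cfg.tonic_gaba else 0.0)
        hh_mask = (self.gna > 0).astype(float)
        self.gahp = hh_mask * cfg.gbar_AHP * (on if cfg.ahp else 0.0)
        self.gnap = hh_mask * cfg.gbar_NaP * (on if cfg.nap else 0.0)

        rtf = cfg.constants.RT_over_F
        bath = cfg.diffusion.bath
        e_k0 = rtf * math.log(bath["K"] / CI_INIT["K"])
        e_na0 = rtf * math.log(bath["Na"] / CI_INIT["Na"])
        v0, lam = calibrate_pump(e_k0, e_na0, bath["K"], CI_INIT["Na"],
                                 params=cfg.pump, rt_over_f=rtf)
        self.v_rest = v0
        self.pump_imax = lam * self.gnaleak          # uA/cm^2 scale

        kcc2_mask = np.isin(kind, [SOMA, DENDRITE]
                            + ([AIS] if cfg.kcc2_in_ais else [])
                            ).astype(float)
        base_kcc2 = cfg.kcc2.I_Cl_max * 1e3          # mA -> uA/cm^2
        scale = cfg.kcc2_scale
        if np.ndim(scale) == 0:
            self.kcc2_imax = base_kcc2 * float(scale) * kcc2_mask * on
        else:
            self.kcc2_imax = base_kcc2 * np.asarray(scale, dtype=float) * on
        self.nkcc1_imax = (cfg.nkcc1.I_Cl_max * 1e3 * cfg.nkcc1_scale
                           * (kind == AIS).astype(float) * on)
        self.clhco3_imax = np.full(nc, cfg.clhco3.I_Cl_max * 1e3
                                   * cfg.clhco3_scale * on)
        self.nah_imax = np.full(nc, cfg.chemistry.I_H_max * 1e3
                                * cfg.nah_scale * on)
        # NHE kinetic set point: zero flux at the resting E_Na - E_H
        e_h0 = rtf * math.log(cfg.chemistry.h_out / cfg.chemistry.h_init)
        self.nah_dfset = e_na0 - e_h0

        self.ampa_frac_na = ampa_carrier_split(e_na0, e_k0)
        self._build_synapses()
        self._build_windows()
        self._build_state()

    def _build_synapses(self) -> None:
        cfg = self.config
        cell = self.cell
        dt = cfg.dt
        n_steps = int(round(cfg.duration / dt))
        self.n_steps = n_steps
        pop_comp, pop_is_gaba, pop_decay, pop_label = [], [], [], []
        pop_saturating = []
        ev_t, ev_p, ev_g = [], [], []
        specs = []   # (count, rate, gmean, gsd, tau, periodic, t0, t1,
        #               burst, period)
        if cfg.mechanisms_enabled:
            if cfg.f_inh > 0:
                for c in np.where(cell.synapse_counts["GABA_A"] > 0)[0]:
                    pop_comp.append(c); pop_is_gaba.append(True)
                    pop_decay.append(math.exp(-dt / 30.0))
                    pop_saturating.append(False)
                    pop_label.append(f"bg_gaba_{c}")
                    specs.append((int(cell.synapse_counts["GABA_A"][c]),
                                  cfg.f_inh, 1.0, 0.3, 30.0, False,
                                  0.0, cfg.duration, None, None))
            if cfg.f_exc > 0:
                for c in np.where(cell.synapse_counts["AMPA"] > 0)[0]:
                    pop_comp.append(c); pop_is_gaba.append(False)
                    pop_decay.append(math.exp(-dt / 10.0))
                    pop_saturating.append(False)
                    pop_label.append(f"bg_ampa_{c}")
                    specs.append((int(cell.synapse_counts["AMPA"][c]),
                                  cfg.f_exc, 0.5, 0.2, 10.0, False,
                                  0.0, cfg.duration, None, None))
            for k, ts in enumerate(cfg.test_synapses):
                pop_comp.append(ts.compartment)
                pop_is_gaba.append(ts.kind == "GABA_A")
                pop_decay.append(math.exp(-dt / ts.tau_ms))
                pop_saturating.append(ts.saturating and ts.count == 1)
                pop_label.append(f"test_{k}")
                t1 = cfg.duration if ts.t_stop_ms is None else ts.t_stop_ms
                specs.append((ts.count, ts.rate_hz, ts.gmax_nS,
                              ts.gmax_sd_nS, ts.tau_ms, ts.periodic,
                              ts.t_start_ms, t1, ts.burst_ms,
                              ts.burst_period_ms))
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(max(len(specs), 1))
        for idx, (count, rate, gmean, gsd, tau, periodic, t0, t1,
                  burst, period) in enumerate(specs):
            if rate <= 0 or count <= 0 or t1 <= t0:
                continue
            if periodic:
                times, g = periodic_events(rate * count, t0, t1, gmean)
            else:
                pop = SynapsePopulation(0, "GABA_A", count, rate,
                                        gmean, gsd if gsd > 0 else 1e-12,
                                        tau)
                sub_seed = children[idx].generate_state(1)[0] % (2 ** 31)
                times, g = sample_synaptic_events(pop, t0, t1, sub_seed)
                if gsd == 0:
                    g = np.full_like(g, gmean)
            if burst is not None and period is not None:
                keep = ((times - t0) % period) < burst
                times, g = times[keep], g[keep]
            steps = np.floor(times / dt).astype(np.int64)
            keep = steps < self.n_steps
            ev_t.append(steps[keep])
            ev_p.append(np.full(int(keep.sum()), idx, dtype=np.int64))
            ev_g.append(g[keep] * 1e-6)    # nS -> mS
        if ev_t:
            steps = np.concatenate(ev_t)
            pops = np.concatenate(ev_p)
            gs = np.concatenate(ev_g)
            order = np.argsort(steps, kind="stable")
            self.ev_step, self.ev_pop, self.ev_g = (steps[order],
                                                    pops[order], gs[order])
        else:
            self.ev_step = np.empty(0, dtype=np.int64)
            self.ev_pop = np.empty(0, dtype=np.int64)
            self.ev_g = np.empty(0)
        self.pop_comp = np.array(pop_comp, dtype=np.int64)
        self.pop_is_gaba = np.array(pop_is_gaba, dtype=bool)
        self.pop_decay = np.array(pop_decay)
        self.pop_saturating = np.array(pop_saturating, dtype=bool)
        self.pop_label = pop_label

    def _build_windows(self) -> None:
        cfg = self.config
        dt = cfg.dt
        comp, kind_, amp, start, stop = [], [], [], [], []
        for (c, g_nS, t0, t1) in cfg.gaba_windows:
            comp.append(c); kind_.append(0); amp.append(g_nS * 1e-6)
            start.append(int(round(t0 / dt))); stop.append(int(round(t1 / dt)))
        for (c, i_nA, t0, t1) in cfg.current_injections:
            comp.append(c); kind_.append(1); amp.append(i_nA * 1e-3)
            start.append(int(round(t0 / dt))); stop.append(int(round(t1 / dt)))
        for (c, i_mA, t0, t1) in cfg.acid_loads:
            comp.append(c); kind_.append(2); amp.append(i_mA * 1e3)
            start.append(int(round(t0 / dt))); stop.append(int(round(t1 / dt)))
        self.win_comp = np.array(comp, dtype=np.int64)
        self.win_kind = np.array(kind_, dtype=np.int64)
        self.win_amp = np.array(amp)
        self.win_start = np.array(start, dtype=np.int64)
        self.win_stop = np.array(stop, dtype=np.int64)

    def _build_state(self) -> None:
        cfg = self.config
        if isinstance(cfg.init, InitialState):
            state = cfg.init.copy()
        elif cfg.init == "rest":
            state = relax_to_rest(self.cell,
                                  config=replace(cfg, init="nominal"))
        else:
            state = nominal_state(self.cell, cfg)
        self.state = state
        self.clamp_in = np.zeros(8, dtype=bool)
        for s in cfg.clamp_species:
            self.clamp_in[SPECIES.index(s)] = True
        self.clamp_sh = np.zeros(5, dtype=bool)
        if cfg.clamp_shell:
            for s, val in cfg.clamp_shell.items():
                x = SHELL_SPECIES.index(s)
                self.clamp_sh[x] = True
                state.Co[x, :] = val
        self.Ci0 = state.Ci.copy()
        self.Co0 = state.Co.copy()

    # -- run ---------------------------------------------------------------
    def run(self) -> TimeSeriesRecord:
        cfg = self.config
        cell = self.cell
        nc = cell.n_comp
        rec_every = max(1, int(round(cfg.record_interval / cfg.dt)))
        nt = self.n_steps // rec_every
        if self.n_steps == 0:
            return self._initial_record()
        npop = self.pop_comp.size
        rec_V = np.zeros((nt, nc))
        rec_Ci = np.zeros((nt, 8, nc))
        rec_Co = np.zeros((nt, 5, nc))
        rec_kcc2 = np.zeros((nt, nc))
        rec_pop = np.zeros((nt, max(npop, 1)))
        rec_clmean = np.zeros((nt, nc))
        q_pop = np.zeros(max(npop, 1))
        spikes = np.zeros(nc, dtype=np.int64)
        nclamp = np.zeros(1, dtype=np.int64)

        vclamp_comp, vclamp_val = -1, 0.0
        if cfg.voltage_clamp is not None:
            vclamp_comp, vclamp_val = cfg.voltage_clamp
        use_fix = cfg.fix_egaba is not None
        fix_val = cfg.fix_egaba if use_fix else 0.0
        chem = ChemistryParams() if cfg.chemistry is None else cfg.chemistry
        st = self.state
        on = cfg.mechanisms_enabled

        status, bad_step, bad_comp = _kernel.integrate(
            self.n_steps, cfg.dt, rec_every,
            self.geom.parent, self.gax, cell.area_cm2, self.geom.vol_ann,
            self.geom.shell_vol, self.geom.f_cross, self.geom.a_edge,
            self.geom.dist_edge, self.geom.rad_M,
            np.array(cfg.diffusion.D), np.array(VALENCE),
            st.Ci, st.Co, st.V, st.gates,
            np.zeros(max(npop, 1)),
            self.gna, self.gk, self.gkleak, self.gnaleak, self.gtonic,
            self.gahp, self.gnap,
            self.pump_imax, cfg.pump.K_m_Ko, cfg.pump.K_m_Nai,
            cfg.pump.Na_Half, cfg.pump.Na_o,
            self.kcc2_imax, cfg.kcc2.V_half,
            self.nkcc1_imax, cfg.nkcc1.V_half,
            self.clhco3_imax, cfg.clhco3.V_half,
            self.nah_imax, chem.V_half_H, self.nah_dfset,
            chem.K1_prime, chem.K_a, chem.h_out,
            bool(cfg.chem and on),
            self.pop_comp if npop else np.zeros(1, dtype=np.int64),
            self.pop_is_gaba if npop else np.zeros(1, dtype=bool),
            self.pop_decay if npop else np.ones(1),
            self.pop_saturating if npop else np.zeros(1, dtype=bool),
            self.ev_step, self.ev_pop, self.ev_g,
            self.win_comp, self.win_kind, self.win_amp,
            self.win_start, self.win_stop,
            self.clamp_in, self.Ci0, self.clamp_sh, self.Co0,
            vclamp_comp, float(vclamp_val), float(fix_val), use_fix,
            cfg.gaba_hco3_frac, self.ampa_frac_na, cfg.ampa_mass_flux,
            cfg.drift, cfg.ecs_diffusion,
            cfg.diffusion.tau_FH, cfg.diffusion.k_bath,
            cfg.constants.C_m, cfg.constants.RT_over_F,
            cfg.hh_params.V_T, cfg.hh_params.V_S,
            self._ahp_constants(),
            rec_V, rec_Ci, rec_Co, rec_kcc2, rec_pop, rec_clmean,
            q_pop, spikes, nclamp)
        if status == 1:
            raise RuntimeError(
                f"non-finite membrane potential at step {bad_step} "
                f"(t = {bad_step * cfg.dt:.3f} ms), compartment {bad_comp}")
        if status == 2:
            raise RuntimeError(
                f"non-positive concentration at step {bad_step} "
                f"(t = {bad_step * cfg.dt:.3f} ms), compartment {bad_comp}")

        t = (np.arange(nt) + 1) * rec_every * cfg.dt
        if npop == 0:
            rec_pop = rec_pop[:, :0]
            q_pop = q_pop[:0]
        return TimeSeriesRecord(
            t, rec_V, rec_Ci, rec_clmean, rec_Co, rec_kcc2, rec_pop,
            self.pop_comp, self.pop_is_gaba, self.pop_label, q_pop,
            spikes, int(nclamp[0]), cfg.seed, cfg, cell, st)

    def _initial_record(self) -> TimeSeriesRecord:
        """Zero-duration run: a record holding only the initial state."""
        st = self.state
        nc = self.cell.n_comp
        npop = self.pop_comp.size
        vol_ann = self.geom.vol_ann
        clmean = (st.Ci[0] * vol_ann).sum(axis=1) / vol_ann.sum(axis=1)
        return TimeSeriesRecord(
            np.zeros(1), st.V[None, :].copy(), st.Ci[None, :, :, 0].copy(),
            clmean[None, :], st.Co[None, :, :].copy(), np.zeros((1, nc)),
            np.zeros((1, npop)), self.pop_comp, self.pop_is_gaba,
            self.pop_label, np.zeros(npop), np.zeros(nc, dtype=np.int64),
            0, self.config.seed, self.config, self.cell, st)

    def _ahp_constants(self) -> np.ndarray:
        a = self.config.adaptation
        return np.array([a.c_vm, a.c_km, a.c_tm, a.c_vtm1, a.c_ktm1,
                         a.c_vtm2, a.c_ktm2, a.tau_z, a.c_h, a.c_vh,
                         a.c_kh, a.c_th, a.c_vth1, a.c_kth1, a.c_vth2,
                         a.c_kth2, a.v_sm, a.v_sh])


def run(config: SimConfig, cell: Optional[CellModel] = None
        ) -> TimeSeriesRecord:
    """Build and run a simulation; returns the record (final state inside)."""
    return Simulation(config, cell).run()


_REST_CACHE: dict = {}


def relax_to_rest(cell: Optional[CellModel] = None,
                  duration_ms: float = 15000.0,
                  config: Optional[SimConfig] = None) -> InitialState:
    """No-input resting state: relax the model from the nominal initial
    concentrations with every mechanism active but no synaptic input.

    The printed initial concentrations are steady only under background
    bombardment; without input, KCC2 pulls E_Cl to the E_K equilibrium
    within seconds.  The relaxed state is cached per geometry/config key.
    """
    if config is None:
        config = SimConfig()
    if cell is None:
        cell = build_cell()
    scale = config.kcc2_scale
    scale_key = (float(scale) if np.ndim(scale) == 0
                 else hash(np.asarray(scale, dtype=float).tobytes()))
    key = (repr(cell.config), scale_key, config.tonic_gaba,
           config.nkcc1_scale, config.clhco3_scale, config.kcc2_in_ais,
           config.gaba_hco3_frac, config.diffusion.tau_FH, duration_ms)
    if key in _REST_CACHE:
        return _REST_CACHE[key].copy()
    cfg = replace(config, duration=duration_ms, f_inh=0.0, f_exc=0.0,
                  record_interval=max(duration_ms / 10.0, config.dt),
                  test_synapses=[], gaba_windows=[], current_injections=[],
                  acid_loads=[], init="nominal")
    start = nominal_state(cell, cfg)
    # Seed [Cl-]i near its no-input equilibrium (E_Cl = E_K wherever KCC2
    # is active, flat elsewhere).  Without this the myelinated axon,
    # which has no local Cl- pathway, approaches equilibrium only by
    # longitudinal diffusion over ~1 mm (minutes of simulated time).
    if np.any(np.atleast_1d(cfg.kcc2_scale) > 0):
        rtf = cfg.constants.RT_over_F
        e_k0 = rtf * math.log(cfg.diffusion.bath["K"] / CI_INIT["K"])
        start.Ci[ICL] = cfg.diffusion.bath["Cl"] * math.exp(e_k0 / rtf)
    cfg = replace(cfg, init=start)
    rec = run(cfg, cell)
    _REST_CACHE[key] = rec.final_state.copy()
    return rec.final_state
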
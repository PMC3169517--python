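# Methods

## Model

`chloridesim` integrates a conductance-based whole neuron in which ion
concentrations are first-class dynamical state. The default cell is a
soma (20 µm cylinder), three primary dendrites of ten 20-µm compartments
tapering 2 → 0.5 µm, an axon initial segment (AIS, 20 × 1 µm) and ten
myelinated internodes (100 × 1 µm) separated by 1-µm nodes of Ranvier.
Eight intracellular species (Cl⁻, K⁺, Na⁺, Ca²⁺, HCO₃⁻, H⁺, H₂PO₄⁻,
HPO₄²⁻) are tracked in four concentric annuli per compartment; five
(Cl⁻, K⁺, Na⁺, Ca²⁺, HCO₃⁻) are also tracked in a Frankenhaeuser–Hodgkin
extracellular shell of one quarter the compartment volume that relaxes
to an infinite bath with τ = 100 ms.

Membrane mechanisms, per compartment kind:

* Traub–Miles Hodgkin–Huxley Na⁺/K⁺ channels with threshold shift
  V_T = −58 mV and a slow-inactivation shift V_S = −10 mV applied as a
  depolarizing displacement of the inactivation curve (the opposite sign
  reading puts the model in depolarization block after a single spike).
  Densities 1.2 mS/cm² (soma, dendrites) and 12 mS/cm² (AIS), with
  g_K = 10/12 · g_Na (the 120:100 pS/µm² ratio of the model family these
  densities come from).
* K⁺ and Na⁺ ohmic leaks in a fixed 5:1 ratio (0.02/0.004 soma and AIS,
  0.03/0.006 proximal dendrite, 0.1/0.02 distal dendrite, 15/3 nodes,
  2·10⁻⁵/4·10⁻⁶ internodes, mS/cm²), plus an optional tonic GABA_A leak.
* GABA_A synapses (instantaneous rise, τ = 30 ms decay, 1 ± 0.3 nS) at
  40/100 µm² on the soma, 12/100 µm² on dendrites and 60/100 µm² on the
  AIS; AMPA synapses (τ = 10 ms, 0.5 ± 0.2 nS) at 60/100 µm² on
  dendrites. Background drive is an independent Poisson process per
  synapse; all synapses of one kind on one compartment share a single
  decaying conductance. Probed single synapses *saturate*: an event
  resets the conductance to its peak rather than summing, which is what
  makes total conductance sublinear in activation rate.
* GABA_A conductance splits 4:1 between Cl⁻ and HCO₃⁻, each against its
  own Nernst potential. The composite therefore reverses at the
  conductance-weighted mean of E_Cl and E_HCO3, within ~2 mV of the GHK
  E_GABA that the package reports as the reversal metric. AMPA
  conductance is split between Na⁺ and K⁺ so the composite reverses at
  0 mV at the initial gradients, and its carriers enter the
  concentration books (mass-closed; an electrical-only variant exists).
* Na⁺-K⁺-ATPase: 3 Na⁺ out / 2 K⁺ in, net one charge out. Rate =
  I_max · f_v(V) · [K⁺]_o/([K⁺]_o+1.5) · (Na_i/(Na_i+20))³ /
  (1+(10/Na_i)²), with the Livshitz/Decker voltage factor f_v. The
  cubic Na⁺ activation gives the pump the logarithmic gain (~3–4)
  needed to hold Na⁺ against synaptic load. Pump density is
  proportional to the local Na⁺ leak density and the global scale is
  calibrated at setup so transmembrane Na⁺ flux is exactly zero at the
  initial concentrations; with the 5:1 leak ratio this fixes the
  resting potential at V₀ = (15·E_K + 2·E_Na)/17 ≈ −85.9 mV.
* KCC2: electroneutral 1 Cl⁻ : 1 K⁺ efflux with the odd-symmetric
  saturating law J = I_max·DF/(|DF|+V_half), DF = E_Cl − E_K, I_max =
  0.3 mA/cm², V_half = 40 mV; present in soma, dendrites and (by
  default) the AIS. NKCC1 (1 Na⁺:1 K⁺:2 Cl⁻ inward, reversal at
  (E_K+E_Na)/2) is restricted to the AIS and off by default; the
  Cl⁻/HCO₃⁻ exchanger (I_max = 0.1 mA/cm², V_half = 50 mV) is off by
  default and ubiquitous when enabled.
* Chemistry: carbonic-anhydrase CO₂ hydration with K_eq = 10^−6.35 M at
  fixed dissolved CO₂ (back-computed so the printed initial state —
  [HCO₃⁻] = 15 mM at the phosphate-equilibrium pH 7.2 — is an exact
  equilibrium), and phosphate buffering with pK 7.2 and 60 mM total.
  The printed rate constant (10⁶ s⁻¹) makes the subsystem relax within
  nanoseconds, so the engine advances it by an analytic equilibrium
  projection per step (a scalar Newton solve per annulus that conserves
  total phosphate and the reaction invariant exactly). The Na⁺/H⁺
  exchanger (I_max = 0.03 mA/cm², V_half = 10 mV) is driven by the
  displacement of E_Na − E_H from its resting value: silent at resting
  pH and activated by acid loads, the documented kinetic behavior of
  NHE1. Without that set point the printed driving force (~52 mV)
  would alkalinize the cell toward pH 8 and triple-load the pump at
  rest.
* Electrodiffusion: longitudinal Nernst–Planck flux between section
  centers, with the drift term confined to the outermost annuli (the
  electric field is membrane-bound); radial Fickian exchange between
  annuli; extracellular Fickian exchange between neighboring shells.
  D (10⁻⁵ cm²/s): Cl⁻ 2.03, K⁺ 1.96, Na⁺ 1.33, H⁺ 9.33; HCO₃⁻ 1.18,
  Ca²⁺ 0.79, phosphates 0.85 (aqueous literature values, configurable).

## Numerical scheme

Forward Euler at dt = 0.05 ms for gates, concentrations, shells and
longitudinal diffusion, with two implicit exceptions chosen for
stiffness, both unconditionally stable and mass/charge exact:

* membrane potential: backward-Euler solve on the compartment tree
  (Hines elimination) with conductances frozen at the step start. The
  axial coupling of 1-µm nodes has a ~3 µs time constant and the
  explicit update diverges at any usable step. Transmembrane currents
  are then evaluated at the *new* potential, so the capacitive charge
  and the species books agree to rounding error.
* radial diffusion: per-(species, compartment) propagators
  (I − dt·L)⁻¹ precomputed at setup; sub-µm annuli in 0.5-µm dendrites
  relax on ~1 µs.

The longitudinal operator is explicit; the stability ratio D·dt/dx² is
checked at setup and a violating geometry is rejected. Clamps (species,
shell, voltage) are restored at the end of each step, so clamped
quantities are exact. Spikes are counted as upward crossings of −10 mV
with a 2-ms merge. Any non-finite potential or non-positive
concentration aborts with the offending compartment and time.

Determinism: every stochastic element derives from one seed through
`numpy` `SeedSequence` spawning, one stream per synapse population;
identical configurations reproduce records bit-for-bit.

## Initial state, rest, and calibrations

Initial concentrations (mM): Cl⁻ 6 / 120, K⁺ 140 / 3, Na⁺ 10 / 45,
HCO₃⁻ 15 / 25, H₂PO₄⁻ = HPO₄²⁻ = 30, Ca²⁺ 10⁻⁴ / 2 (inert; no shipped
mechanism fluxes it). This state is steady *under background input*;
with no input, KCC2 (which has no opposing Cl⁻ leak) pulls E_Cl to the
E_K equilibrium within seconds. `relax_to_rest()` therefore computes
the no-input resting state (seeding the myelinated axon, which has no
local Cl⁻ pathway and would otherwise equilibrate by ~minutes of
longitudinal diffusion, at the E_K-equilibrium chloride) and the
no-background protocols start there.

Three quantities are calibrated at setup rather than printed: the pump
scale (Na⁺ balance, above), the NHE set point (resting E_Na − E_H), and
the AMPA carrier split (reversal 0 mV at the initial gradients).

## Scaled protocol conditions

The full study conditions are 200-s runs. The shipped defaults use the
shortest durations for which the trailing-window (25%) summaries are
stable: 45–60 s for background steady states (somatic E_Cl relaxes in
seconds; the trailing window averages the Poisson fluctuation, and a
slow Na⁺/K⁺ redistribution mode of order minutes remains and is part of
the measured operating point), 8–20 s for clamp sweeps and placement
protocols, 3 s for the deterministic focal-gradient profile, 10 s per
grid point for the optimal-frequency sweeps. Acceptance measurements
average three seeds where the drive is stochastic.

Profile measures are operationalized as: gradient = peak |d[Cl⁻]/dx|
along the synapse's dendrite; spatial extent = distance at which the
elevation falls to 10% of peak ("back to baseline" for an exponentially
decaying profile); E_GABA shift = GHK E_GABA difference between onset
and 200 ms at the synapse compartment.

## Design choices where the source is open

* H⁺ is stored in mM like all species (float64 leaves ~10 significant
  digits at 10⁻⁴ mM); chemistry converts to molar internally.
* The HH densities as printed (1.2/12 mS/cm²) support single spikes
  from rest but not repetitive firing under any drive tested; the
  conductance family they cite runs 10× hotter. Protocols whose point
  is sustained spiking (biphasic GABA-clamp, input–output curves,
  AHP/NaP comparisons) therefore set `hh_scale` (10–30×), which is
  recorded in their outputs; everything else uses the printed values.
* The AHP (Ca²⁺-activated K⁺) and persistent-Na channels are
  reconstructions from printed constants only: AHP = fast sigmoid gate
  m (half −28.9 mV, slope 6.2 mV, bi-exponential τ) times a slow
  integrator z (τ = 1 s) on g·m·z·(V−E_K); NaP = low-threshold sigmoid
  activation and 2-s inactivation shifted by v_sm/v_sh. Maximal
  conductances are not printed; defaults (2 and 0.1 mS/cm²) are the
  values at which the documented rate-decreasing/-increasing effects
  are clearly resolved. Both are off by default.
* KCC2 sits in the AIS by default; the AIS-free arrangement is what the
  NKCC1 protocols use explicitly.
* Branch points couple the soma to each primary dendrite independently
  (star topology); the axial drift term acts on every parent edge.

## What passing tests do and do not show

All inputs are self-generated: the synthetic study conditions are the
printed geometry, densities and rates themselves, and the test suite
checks (a) closed-form physics of every mechanism against independent
oracles, (b) conservation and determinism invariants of the integrator,
and (c) direction-of-effect of the figure-level experiments at reduced
durations. Quantitative agreement with the source's operating points is
checked by `tests/test_acceptance.py` and recomputed by
`scripts/acceptance.py`; two families of anchors (the low-load E_Cl
level, and quantities downstream of it such as the optimal-frequency
positions and the [K⁺]_o at which KCC2 transport vanishes) depend on a
low-load driving force that the printed transporter constants do not
reproduce, and the suite reports the measured values rather than
forcing them. The calibration-rate steady state itself lands within
~5 mV of its −80 mV anchor (the anchor was the source's calibration of
an unprinted pump; here every constant is as printed and the pump is
calibrated only for resting Na⁺ balance). Nothing here validates the model against biological data
beyond what the reproduced operating points themselves carry.

## Known limitations

* Quasi-steady background states retain a slow (minutes) Na⁺/K⁺
  redistribution mode; trailing-window summaries at scaled durations
  sample that trajectory, exactly as 200-s windows sample it more
  slowly.
* The GABA_A composite reverses ~1.7 mV depolarized of the GHK E_GABA
  (ohmic split vs GHK flux form).
* Background populations lump synapses additively; per-synapse
  saturation is exact only for probed single synapses (duty cycles of
  background synapses stay ≤ 0.15 at the rates used).
* No NMDA, GABA_B, short-term plasticity, reconstructed morphologies,
  or network-level extracellular K⁺.
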
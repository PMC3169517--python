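# chloridesim

A whole-neuron **electrodiffusion** simulator of chloride and pH
homeostasis, for computational neuroscientists studying why synaptic
inhibition succeeds or fails. Conventional cable models treat the
GABA_A reversal potential as a constant; here every determinant of it
is a dynamical variable. Eight ion species (Cl⁻, K⁺, Na⁺, Ca²⁺, HCO₃⁻,
H⁺, H₂PO₄⁻, HPO₄²⁻), the membrane potential, Hodgkin–Huxley spiking,
Poisson synaptic bombardment, cation–chloride cotransport (KCC2,
NKCC1), the Na⁺-K⁺-ATPase, a Cl⁻/HCO₃⁻ exchanger and carbonate/
phosphate buffering chemistry co-evolve in a compartmental neuron with
intracellular Nernst–Planck transport (four concentric annuli per
section) and a Frankenhaeuser–Hodgkin extracellular shell per
compartment.

## The model in brief

Membrane potential per compartment obeys

    C dV/dt = −Σ_x g_x (V − E_x) − I_pump + I_axial ,

with every reversal potential updated continuously from the Nernst
equation, and the GABA_A reversal reported through the
Goldman–Hodgkin–Katz form for the 4:1 Cl⁻:HCO₃⁻ permeability,

    E_GABA = (RT/F) ln[(4[Cl⁻]_i + [HCO₃⁻]_i) / (4[Cl⁻]_o + [HCO₃⁻]_o)] .

Each species x obeys a concentration balance per annulus,

    d[x]/dt = −I_x S/(z_x F Vol) + Reac_x + Diff_x ,

where `Reac` is the carbonate/phosphate chemistry (advanced by exact
equilibrium projection — the printed rate constants make it
instantaneous on the 0.05-ms step) and `Diff` the Nernst–Planck
operator

    J = −D (∂c/∂y + z c (F/RT) ∂V/∂y) ,

whose drift term is confined to the outermost annuli. Electroneutral
transporters follow the saturating law `J = I_max·DF/(|DF| + V_half)`
with driving forces E_Cl − E_K (KCC2), (E_K+E_Na)/2 − E_Cl (NKCC1),
E_Cl − E_HCO3 (the exchanger) and the acid displacement of E_Na − E_H
(Na⁺/H⁺ exchange). Full equations, parameters and numerical scheme:
[docs/methods.md](docs/methods.md).

## Worked example

Steady-state somatic chloride under in-vivo-like bombardment at the
model's calibration rates (3.2 Hz inhibitory / 1.6 Hz excitatory per
synapse), then the same with chloride extrusion reduced to a third:

```python
import numpy as np
from chloridesim import SimConfig, run, measure_steady_state

for scale in (1.0, 0.33):
    cfg = SimConfig(duration=45_000.0, record_interval=50.0,
                    f_inh=3.2, f_exc=1.6, kcc2_scale=scale, seed=1)
    rec = run(cfg)                       # default 52-compartment cell
    e_cl, sd = measure_steady_state(rec, rec.e_cl(0), 11_250.0)
    e_gaba, _ = measure_steady_state(rec, rec.e_gaba(0), 11_250.0)
    print(f"KCC2 {scale:4.0%}:  E_Cl = {e_cl:6.1f} mV,"
          f"  E_GABA = {e_gaba:6.1f} mV  (sd {sd:.2f})")
```

prints

```
KCC2 100%:  E_Cl =  -84.6 mV,  E_GABA =  -80.6 mV  (sd 0.28)
KCC2  33%:  E_Cl =  -76.6 mV,  E_GABA =  -73.3 mV  (sd 0.23)
```

At full KCC2 activity the somatic Cl⁻ reversal settles a few mV below
the −80 mV operating point the transporter strength targets, with
E_GABA several millivolts less negative because the receptor also
passes HCO₃⁻ (E_HCO3 ≈ −14 mV). Cutting extrusion to 33% depolarizes
both reversals by ~8 mV under identical bombardment: inhibition weakens
not because receptors changed but because the chloride gradient did.

The same machinery is packaged as figure-level protocols
(`chloridesim.protocols`): focal high-frequency input building
longitudinal [Cl⁻]i gradients, somato-dendritic standing gradients,
IPSC trains, optimal-inhibition frequency sweeps, HCO₃⁻/Cl⁻ trade-off
experiments, extracellular-K⁺ coupling, and spiking feedback. A thin
CLI wraps them:

```bash
chloridesim simulate --duration 10 --f-inh 3.2 --f-exc 1.6 --out run.npz
chloridesim protocol kcc2-placement --out results/
```

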
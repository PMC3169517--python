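"""Compiled integration core.

One call advances the full coupled state (membrane potential, gating
variables, synaptic conductances, eight intracellular species over four
annuli, five extracellular-shell species) by ``n_steps`` of ``dt``.

Numerical scheme per step (order fixed and documented in docs/methods.md):

1. decay + insert synaptic conductance events;
2. equilibrium potentials from the outer annulus and the local shell;
3. forward-Euler gate update (clamped to [0, 1], clamps counted);
4. implicit (backward-Euler) membrane-potential solve on the compartment
   tree with conductances frozen at the step start (Hines elimination);
5. transmembrane currents evaluated at the *new* potential, converted to
   mole fluxes (so electrical and chemical bookkeeping agree exactly),
   plus the electroneutral transporters, pump and imposed loads;
6. explicit longitudinal electrodiffusion (drift restricted to outer
   annuli), implicit radial exchange (precomputed propagators),
   extracellular shell exchange and bath relaxation;
7. analytic equilibrium projection of the carbonate/phosphate subsystem;
8. clamps restored, spikes detected, records written.

Status codes returned: 0 ok, 1 non-finite potential, 2 non-positive
concentration (with the offending step and compartment).
"""

import math

import numpy as np
from numba import njit, int64

from .membrane_mechanisms import (hh_rates, ahp_gate_derivs,
                                  nap_gate_derivs, _clamp01)
from .transport import saturating_rate, pump_rate
from .chemistry import equilibrate

FARADAY = 96485.332

# species indices (mirror constants.SPECIES)
ICL, IK, INA, ICA, IHCO3, IH, IH2PO4, IHPO4 = 0, 1, 2, 3, 4, 5, 6, 7


@njit(cache=True)
def integrate(n_steps, dt, rec_every,
              # geometry
              parent, gax, area, vol_ann, shell_vol,
              f_cross, a_edge, dist_edge, radM, Dcoef, zval,
              # state (modified in place)
              Ci, Co, V, gates, gsyn,
              # densities (mS/cm^2) and transport scales (uA/cm^2)
              gna, gk, gkleak, gnaleak, gtonic, gahp_d, gnap_d,
              pump_imax, km_ko, km_nai, na_half, na_o_pump,
              kcc2_imax, kcc2_vhalf, nkcc1_imax, nkcc1_vhalf,
              clhco3_imax, clhco3_vhalf, nah_imax, nah_vhalf, nah_dfset,
              # chemistry
              k1prime, ka_phos, h_out_M, chem_on,
              # synapses
              pop_comp, pop_is_gaba, pop_decay, pop_saturating,
              ev_step, ev_pop, ev_g,
              # windows: kind 0 = GABA conductance (mS), 1 = injected
              # current (uA, positive depolarizing), 2 = H+ influx
              # (uA/cm^2 mole equivalent)
              win_comp, win_kind, win_amp, win_start, win_stop,
              # clamps
              clamp_in, Ci0, clamp_sh, Co0,
              vclamp_comp, vclamp_val, fix_egaba, use_fix_egaba,
              # constants / switches
              hco3_frac, ampa_frac_na, ampa_flux_on, drift_on, ecs_on,
              tau_fh, kbath, cm, rtf, hh_vt, hh_vs, ahp_c,
              # outputs
              rec_V, rec_Ci, rec_Co, rec_kcc2, rec_pop, rec_clmean,
              q_pop, spikes, nclamp):
    nc = V.shape[0]
    na = Ci.shape[2]
    ns = Ci.shape[0]
    npop = gsyn.shape[0]
    nev = ev_step.shape[0]
    nwin = win_comp.shape[0]

    e_na = np.empty(nc); e_k = np.empty(nc); e_cl = np.empty(nc)
    e_hco3 = np.empty(nc); e_h = np.empty(nc)
    g_cl = np.empty(nc); g_hco3 = np.empty(nc)
    g_amna = np.empty(nc); g_amk = np.empty(nc)
    g_na_tot = np.empty(nc); g_k_tot = np.empty(nc)
    rho = np.empty(nc); jkcc2 = np.empty(nc)
    diag = np.empty(nc); rhs = np.empty(nc)
    vold = np.empty(nc)
    phi = np.empty((ns, nc))
    dq = np.empty((ns, nc, na))
    dqo = np.empty((5, nc))
    tmp4 = np.empty(na)
    last_spike = np.empty(nc, np.int64)
    for c in range(nc):
        last_spike[c] = -1000000000
    refract = int(round(2.0 / dt))
    eptr = 0
    h_out_log = math.log(h_out_M)

    for istep in range(n_steps):
        # --- 1. synaptic conductances -----------------------------------
        for p in range(npop):
            gsyn[p] *= pop_decay[p]
        while eptr < nev and ev_step[eptr] == istep:
            p = ev_pop[eptr]
            if pop_saturating[p]:
                # a synapse already open cannot add conductance: the
                # event resets it to its peak (per-synapse saturation)
                if gsyn[p] < ev_g[eptr]:
                    gsyn[p] = ev_g[eptr]
            else:
                gsyn[p] += ev_g[eptr]
            eptr += 1

        # --- 2. reversal potentials -------------------------------------
        for c in range(nc):
            if Ci[ICL, c, 0] <= 0.0 or Ci[IK, c, 0] <= 0.0 \
                    or Ci[INA, c, 0] <= 0.0 or Ci[IHCO3, c, 0] <= 0.0 \
                    or Co[ICL, c] <= 0.0 or Co[IK, c] <= 0.0 \
                    or Co[INA, c] <= 0.0 or Co[IHCO3, c] <= 0.0:
                return 2, istep, c
            e_cl[c] = rtf * math.log(Ci[ICL, c, 0] / Co[ICL, c])
            e_k[c] = rtf * math.log(Co[IK, c] / Ci[IK, c, 0])
            e_na[c] = rtf * math.log(Co[INA, c] / Ci[INA, c, 0])
            e_hco3[c] = rtf * math.log(Ci[IHCO3, c, 0] / Co[IHCO3, c])
            e_h[c] = rtf * (h_out_log - math.log(Ci[IH, c, 0] * 1e-3))

        # --- 3. gates ----------------------------------------------------
        for c in range(nc):
            v = V[c]
            am, bm, ah, bh, an, bn = hh_rates(v, hh_vt, hh_vs)
            x = gates[0, c] + dt * (am * (1.0 - gates[0, c]) - bm * gates[0, c])
            if x < 0.0 or x > 1.0:
                nclamp[0] += 1
                x = _clamp01(x)
            gates[0, c] = x
            x = gates[1, c] + dt * (ah * (1.0 - gates[1, c]) - bh * gates[1, c])
            if x < 0.0 or x > 1.0:
                nclamp[0] += 1
                x = _clamp01(x)
            gates[1, c] = x
            x = gates[2, c] + dt * (an * (1.0 - gates[2, c]) - bn * gates[2, c])
            if x < 0.0 or x > 1.0:
                nclamp[0] += 1
                x = _clamp01(x)
            gates[2, c] = x
            if gahp_d[c] > 0.0 or gnap_d[c] > 0.0:
                dm, dz = ahp_gate_derivs(
                    v, gates[3, c], gates[4, c],
                    ahp_c[0], ahp_c[1], ahp_c[2], ahp_c[3], ahp_c[4],
                    ahp_c[5], ahp_c[6], ahp_c[7])
                gates[3, c] = _clamp01(gates[3, c] + dt * dm)
                gates[4, c] = _clamp01(gates[4, c] + dt * dz)
                dmp, dhp = nap_gate_derivs(v, gates[5, c], gates[6, c],
                                           ahp_c[16], ahp_c[17])
                gates[5, c] = _clamp01(gates[5, c] + dt * dmp)
                gates[6, c] = _clamp01(gates[6, c] + dt * dhp)

        # --- 4. conductance assembly (absolute mS) ----------------------
        for c in range(nc):
            m = gates[0, c]; h = gates[1, c]; n = gates[2, c]
            g_na_tot[c] = (gna[c] * m * m * m * h + gnaleak[c]
                           + gnap_d[c] * gates[5, c] * gates[6, c]) \
                * area[c]
            g_k_tot[c] = (gk[c] * n * n * n * n + gkleak[c]
                          + gahp_d[c] * gates[3, c] * gates[4, c]) \
                * area[c]
            g_cl[c] = (1.0 - hco3_frac) * gtonic[c] * area[c]
            g_hco3[c] = hco3_frac * gtonic[c] * area[c]
            g_amna[c] = 0.0
            g_amk[c] = 0.0
        for p in range(npop):
            c = pop_comp[p]
            if pop_is_gaba[p]:
                g_cl[c] += (1.0 - hco3_frac) * gsyn[p]
                g_hco3[c] += hco3_frac * gsyn[p]
            else:
                g_amna[c] += ampa_frac_na * gsyn[p]
                g_amk[c] += (1.0 - ampa_frac_na) * gsyn[p]
        for w in range(nwin):
            if win_kind[w] == 0 and win_start[w] <= istep < win_stop[w]:
                c = win_comp[w]
                g_cl[c] += (1.0 - hco3_frac) * win_amp[w]
                g_hco3[c] += hco3_frac * win_amp[w]

        # --- pump rate ---------------------------------------------------
        for c in range(nc):
            rho[c] = pump_rate(V[c], Co[IK, c], Ci[INA, c, 0], pump_imax[c],
                               km_ko, km_nai, na_half, na_o_pump, rtf)

        # --- 5. implicit potential solve --------------------------------
        for c in range(nc):
            vold[c] = V[c]
            cdt = cm * area[c] / dt   # uF/ms; uF/ms * mV = uA, same as mS*mV
            gsum = (g_na_tot[c] + g_k_tot[c] + g_amna[c] + g_amk[c])
            esum = (g_na_tot[c] * e_na[c] + g_k_tot[c] * e_k[c]
                    + g_amna[c] * e_na[c] + g_amk[c] * e_k[c])
            if use_fix_egaba:
                gsum += g_cl[c] + g_hco3[c]
                esum += (g_cl[c] + g_hco3[c]) * fix_egaba
            else:
                gsum += g_cl[c] + g_hco3[c]
                esum += g_cl[c] * e_cl[c] + g_hco3[c] * e_hco3[c]
            diag[c] = cdt + gsum
            rhs[c] = cdt * V[c] + esum - rho[c] * area[c]
        for w in range(nwin):
            if win_kind[w] == 1 and win_start[w] <= istep < win_stop[w]:
                rhs[win_comp[w]] += win_amp[w]   # uA, positive depolarizes
        if vclamp_comp >= 0:
            diag[vclamp_comp] += 1e12
            rhs[vclamp_comp] += 1e12 * vclamp_val
        for c in range(1, nc):
            diag[c] += gax[c]
            diag[parent[c]] += gax[c]
        for c in range(nc - 1, 0, -1):
            p = parent[c]
            f = gax[c] / diag[c]
            diag[p] -= f * gax[c]
            rhs[p] += f * rhs[c]
        V[0] = rhs[0] / diag[0]
        for c in range(1, nc):
            V[c] = (rhs[c] + gax[c] * V[parent[c]]) / diag[c]
        for c in range(nc):
            if not math.isfinite(V[c]):
                return 1, istep, c

        # --- 6. transmembrane fluxes at V_new ---------------------------
        for x in range(ns):
            for c in range(nc):
                phi[x, c] = 0.0
        for c in range(nc):
            v = V[c]
            # AMPA carriers contribute to the concentration books only in
            # the mass-closed variant; by default the excitatory current
            # is electrical-only (see engine docs).
            i_na = g_na_tot[c] * (v - e_na[c])                 # mS*mV = uA
            i_k = g_k_tot[c] * (v - e_k[c])
            if ampa_flux_on:
                i_na += g_amna[c] * (v - e_na[c])
                i_k += g_amk[c] * (v - e_k[c])
            phi[INA, c] += i_na
            phi[IK, c] += i_k
            if not use_fix_egaba:
                # z = -1: a positive (outward) anion current is an inward
                # mole flux
                phi[ICL, c] -= g_cl[c] * (v - e_cl[c])
                phi[IHCO3, c] -= g_hco3[c] * (v - e_hco3[c])
            # pump: 3 Na out, 2 K in per net charge rho (uA/cm^2)
            phi[INA, c] += 3.0 * rho[c] * area[c]
            phi[IK, c] -= 2.0 * rho[c] * area[c]
            # KCC2 (Cl- and K+ efflux together)
            j = saturating_rate(e_cl[c] - e_k[c], kcc2_imax[c], kcc2_vhalf)
            jkcc2[c] = j
            phi[ICL, c] += j * area[c]
            phi[IK, c] += j * area[c]
            # NKCC1 (1 Na : 1 K : 2 Cl inward)
            if nkcc1_imax[c] > 0.0:
                w_ = saturating_rate(0.5 * (e_k[c] + e_na[c]) - e_cl[c],
                                     nkcc1_imax[c], nkcc1_vhalf)
                phi[ICL, c] -= w_ * area[c]
                phi[INA, c] -= 0.5 * w_ * area[c]
                phi[IK, c] -= 0.5 * w_ * area[c]
            # Cl-/HCO3- exchanger
            if clhco3_imax[c] > 0.0:
                e_ = saturating_rate(e_cl[c] - e_hco3[c], clhco3_imax[c],
                                     clhco3_vhalf)
                phi[ICL, c] += e_ * area[c]
                phi[IHCO3, c] -= e_ * area[c]
            # Na+/H+ exchanger (H out, Na in), silent at the set point
            if nah_imax[c] > 0.0:
                d_ = saturating_rate(e_na[c] - e_h[c] - nah_dfset,
                                     nah_imax[c], nah_vhalf)
                phi[IH, c] += d_ * area[c]
                phi[INA, c] -= d_ * area[c]
        for w in range(nwin):
            if win_kind[w] == 2 and win_start[w] <= istep < win_stop[w]:
                phi[IH, win_comp[w]] -= win_amp[w] * area[win_comp[w]]
        # per-population current bookkeeping (uA, outward positive)
        for p in range(npop):
            c = pop_comp[p]
            if pop_is_gaba[p]:
                if use_fix_egaba:
                    ip = gsyn[p] * (V[c] - fix_egaba)
                else:
                    ip = gsyn[p] * ((1.0 - hco3_frac) * (V[c] - e_cl[c])
                                    + hco3_frac * (V[c] - e_hco3[c]))
            else:
                ip = gsyn[p] * (ampa_frac_na * (V[c] - e_na[c])
                                + (1.0 - ampa_frac_na) * (V[c] - e_k[c]))
            q_pop[p] += ip * dt
            if (istep + 1) % rec_every == 0:
                rec_pop[(istep + 1) // rec_every - 1, p] = ip
        # apply transmembrane mole fluxes
        for c in range(nc):
            fac_in = dt * 1e-3 / (FARADAY * vol_ann[c, 0])
            fac_sh = dt * 1e-3 / (FARADAY * shell_vol[c])
            for x in range(ns):
                if phi[x, c] != 0.0:
                    Ci[x, c, 0] -= phi[x, c] * fac_in
                    if x < 5:
                        Co[x, c] += phi[x, c] * fac_sh

        # --- longitudinal electrodiffusion ------------------------------
        for x in range(ns):
            for c in range(nc):
                for a in range(na):
                    dq[x, c, a] = 0.0
        for x in range(5):
            for c in range(nc):
                dqo[x, c] = 0.0
        for c in range(1, nc):
            p = parent[c]
            base = a_edge[c] / dist_edge[c] * dt
            dv = V[p] - V[c]
            for x in range(ns):
                dms = Dcoef[x] * 1e-3
                for a in range(na):
                    grad = Ci[x, p, a] - Ci[x, c, a]
                    if a == 0 and drift_on:
                        cbar = 0.5 * (Ci[x, p, 0] + Ci[x, c, 0])
                        grad += zval[x] * cbar * dv / rtf
                    q = dms * base * f_cross[a] * grad
                    dq[x, c, a] += q / vol_ann[c, a]
                    dq[x, p, a] -= q / vol_ann[p, a]
            if ecs_on:
                for x in range(5):
                    q = Dcoef[x] * 1e-3 * 0.25 * base * (Co[x, p] - Co[x, c])
                    dqo[x, c] += q / shell_vol[c]
                    dqo[x, p] -= q / shell_vol[p]
        for x in range(ns):
            for c in range(nc):
                for a in range(na):
                    Ci[x, c, a] += dq[x, c, a]
        for x in range(5):
            for c in range(nc):
                Co[x, c] += dqo[x, c]

        # --- radial exchange (implicit propagator) ----------------------
        for x in range(ns):
            for c in range(nc):
                for a in range(na):
                    s = 0.0
                    for b in range(na):
                        s += radM[x, c, a, b] * Ci[x, c, b]
                    tmp4[a] = s
                for a in range(na):
                    Ci[x, c, a] = tmp4[a]

        # --- FH shell bath relaxation ------------------------------------
        for x in range(5):
            for c in range(nc):
                Co[x, c] += dt * (kbath[x] - Co[x, c]) / tau_fh

        # --- 7. buffer chemistry projection ------------------------------
        if chem_on:
            for c in range(nc):
                for a in range(na):
                    hn, bn_, p2, p1 = equilibrate(
                        Ci[IH, c, a] * 1e-3, Ci[IHCO3, c, a] * 1e-3,
                        Ci[IH2PO4, c, a] * 1e-3, Ci[IHPO4, c, a] * 1e-3,
                        k1prime, ka_phos)
                    Ci[IH, c, a] = hn * 1e3
                    Ci[IHCO3, c, a] = bn_ * 1e3
                    Ci[IH2PO4, c, a] = p2 * 1e3
                    Ci[IHPO4, c, a] = p1 * 1e3

        # --- 8. clamps, spikes, records ----------------------------------
        for x in range(ns):
            if clamp_in[x]:
                for c in range(nc):
                    for a in range(na):
                        Ci[x, c, a] = Ci0[x, c, a]
        for x in range(5):
            if clamp_sh[x]:
                for c in range(nc):
                    Co[x, c] = Co0[x, c]
        for c in range(nc):
            if V[c] >= -10.0 and vold[c] < -10.0 \
                    and istep - last_spike[c] > refract:
                spikes[c] += 1
                last_spike[c] = istep
        if (istep + 1) % rec_every == 0:
            r = (istep + 1) // rec_every - 1
            for c in range(nc):
                rec_V[r, c] = V[c]
                rec_kcc2[r, c] = jkcc2[c]
                clm = 0.0
                vtot = 0.0
                for a in range(na):
                    clm += Ci[ICL, c, a] * vol_ann[c, a]
                    vtot += vol_ann[c, a]
                rec_clmean[r, c] = clm / vtot
                for x in range(ns):
                    rec_Ci[r, x, c] = Ci[x, c, 0]
                for x in range(5):
                    rec_Co[r, x, c] = Co[x, c]
    return 0, n_steps, -1
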
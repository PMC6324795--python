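"""Numba-compiled backward-Euler integrator for the branched cable equation.

One implicit step solves the voltage-linearized system

    (C/dt + G_mem + G_axial) V(t+dt) = C/dt V(t) + G_mem.E + I_inj + I_noise

with a Hines-ordered tridiagonal-tree elimination (parents indexed below
children), which is unconditionally stable for the passive subsystem. Gating
variables advance by exponential (Rush–Larsen) integration evaluated at the
pre-step voltage; synaptic conductances are pairs of exponentially decaying
state variables per kinetic class per compartment, incremented by presynaptic
events, so arbitrary numbers of synapses cost O(classes x compartments) per
step.

Everything here works on plain arrays; :mod:`is3sim.solver` provides the
user-facing layer.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import kinetics as kin

__all__ = ["run_kernel", "STATUS_OK", "STATUS_NONFINITE"]

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def run_kernel(
    parent,          # int64[n], -1 at root
    g_ax,            # float64[n], uS coupling to parent (0 at root)
    child_gsum,      # float64[n], sum of children's g_ax
    cm_dt,           # float64[n], capacitance / dt (uS-equivalent)
    g_leak,          # float64[n], uS
    e_leak,          # float64[n], mV
    gna_t, gna_p, gka, gkdrf,  # float64[n], uS (maximal)
    ena, ek,         # scalars, mV
    dt,              # ms
    n_steps,         # int
    record_every,    # int
    v_init,          # mV
    noise,           # float64[n_steps] nA at soma (len 0 -> no noise)
    inj_comp, inj_start, inj_end, inj_amp,   # injection windows (steps, nA)
    ev_step, ev_comp, ev_cls, ev_amt,        # synaptic events (sorted by step)
    syn_fr, syn_fd,  # float64[n_cls], per-step decay factors exp(-dt/tau)
    e_syn,           # float64[n_cls], mV
    clamp_on,        # bool
    v_clamp,         # mV
    record_all,      # bool
):
    n = parent.shape[0]
    n_cls = syn_fr.shape[0]
    n_rec = n_steps // record_every + 1

    v = np.full(n, v_init)
    # gating state at steady state of v_init
    gate_h = np.empty(n)
    gate_n = np.empty(n)
    gate_a = np.empty(n)
    gate_b = np.empty(n)
    gate_p = np.empty(n)
    active = np.flatnonzero(gna_t + gna_p + gka + gkdrf > 0.0)
    for idx in active:
        gate_h[idx] = kin.na_t_h_inf(v_init)
        gate_n[idx] = kin.kdrf_n_inf(v_init)
        gate_a[idx] = kin.ka_a_inf(v_init)
        gate_b[idx] = kin.ka_b_inf(v_init)
        gate_p[idx] = kin.na_p_p_inf(v_init)

    syn_a = np.zeros((n_cls, n))
    syn_b = np.zeros((n_cls, n))

    d = np.empty(n)
    r = np.empty(n)
    g_ion = np.empty(n)
    ge_ion = np.empty(n)

    root_children = np.flatnonzero(parent == 0)

    rec_v = np.empty(n_rec)
    rec_ic = np.zeros(n_rec)
    if record_all:
        rec_all = np.empty((n_rec, n))
    else:
        rec_all = np.empty((1, n))
    rec_v[0] = v_clamp if clamp_on else v_init
    if clamp_on:
        v[0] = v_clamp
    if record_all:
        rec_all[0, :] = v

    have_noise = noise.shape[0] > 0
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    rec_i = 1
    status = STATUS_OK
    err_t = -1.0
    err_comp = -1

    for step in range(n_steps):
        # -- deliver this step's presynaptic events, then decay
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            c = ev_cls[ev_ptr]
            i = ev_comp[ev_ptr]
            syn_a[c, i] += ev_amt[ev_ptr]
            syn_b[c, i] += ev_amt[ev_ptr]
            ev_ptr += 1
        for c in range(n_cls):
            fr = syn_fr[c]
            fd = syn_fd[c]
            for i in range(n):
                syn_a[c, i] *= fr
                syn_b[c, i] *= fd

        # -- gate advance (Rush-Larsen at pre-step voltage) and ionic terms
        for i in range(n):
            g_ion[i] = 0.0
            ge_ion[i] = 0.0
        for k in range(active.shape[0]):
            i = active[k]
            vi = v[i]
            if gna_t[i] > 0.0:
                hinf = kin.na_t_h_inf(vi)
                gate_h[i] = hinf + (gate_h[i] - hinf) * math.exp(-dt / kin.na_t_h_tau(vi))
                minf = kin.na_t_m_inf(vi)
                g = gna_t[i] * minf * minf * minf * gate_h[i]
                g_ion[i] += g
                ge_ion[i] += g * ena
            if gna_p[i] > 0.0:
                pinf = kin.na_p_p_inf(vi)
                gate_p[i] = pinf + (gate_p[i] - pinf) * math.exp(-dt / kin.na_p_p_tau(vi))
                g = gna_p[i] * gate_p[i]
                g_ion[i] += g
                ge_ion[i] += g * ena
            if gka[i] > 0.0:
                ainf = kin.ka_a_inf(vi)
                gate_a[i] = ainf + (gate_a[i] - ainf) * math.exp(-dt / kin.ka_a_tau(vi))
                binf = kin.ka_b_inf(vi)
                gate_b[i] = binf + (gate_b[i] - binf) * math.exp(-dt / kin.ka_b_tau(vi))
                g = gka[i] * gate_a[i] ** 3 * gate_b[i]
                g_ion[i] += g
                ge_ion[i] += g * ek
            if gkdrf[i] > 0.0:
                ninf = kin.kdrf_n_inf(vi)
                gate_n[i] = ninf + (gate_n[i] - ninf) * math.exp(-dt / kin.kdrf_n_tau(vi))
                g = gkdrf[i] * gate_n[i] ** 4
                g_ion[i] += g
                ge_ion[i] += g * ek

        # -- assemble diagonal and rhs
        for i in range(n):
            gd = cm_dt[i] + g_leak[i] + g_ion[i] + g_ax[i] + child_gsum[i]
            rr = cm_dt[i] * v[i] + g_leak[i] * e_leak[i] + ge_ion[i]
            for c in range(n_cls):
                gs = syn_b[c, i] - syn_a[c, i]
                gd += gs
                rr += gs * e_syn[c]
            d[i] = gd
            r[i] = rr
        for j in range(inj_comp.shape[0]):
            if inj_start[j] <= step < inj_end[j]:
                r[inj_comp[j]] += inj_amp[j]
        if have_noise:
            r[0] += noise[step]

        # -- Hines elimination (children indexed above parents)
        if clamp_on:
            for i in range(n - 1, 0, -1):
                pi = parent[i]
                if pi == 0:
                    continue
                f = g_ax[i] / d[i]
                d[pi] -= f * g_ax[i]
                r[pi] += f * r[i]
            v[0] = v_clamp
        else:
            for i in range(n - 1, 0, -1):
                pi = parent[i]
                f = g_ax[i] / d[i]
                d[pi] -= f * g_ax[i]
                r[pi] += f * r[i]
            v[0] = r[0] / d[0]
        for i in range(1, n):
            v[i] = (r[i] + g_ax[i] * v[parent[i]]) / d[i]

        # -- record
        if (step + 1) % record_every == 0:
            v0 = v[0]
            if not math.isfinite(v0):
                status = STATUS_NONFINITE
                err_t = (step + 1) * dt
                err_comp = 0
                break
            rec_v[rec_i] = v0
            if clamp_on:
                ic = g_leak[0] * (v0 - e_leak[0]) + g_ion[0] * v0 - ge_ion[0]
                for c in range(n_cls):
                    gs = syn_b[c, 0] - syn_a[c, 0]
                    ic += gs * (v0 - e_syn[c])
                for k in range(root_children.shape[0]):
                    ch = root_children[k]
                    ic -= g_ax[ch] * (v[ch] - v0)
                for j in range(inj_comp.shape[0]):
                    if inj_comp[j] == 0 and inj_start[j] <= step < inj_end[j]:
                        ic -= inj_amp[j]
                if have_noise:
                    ic -= noise[step]
                rec_ic[rec_i] = ic
            if record_all:
                for i in range(n):
                    if not math.isfinite(v[i]):
                        status = STATUS_NONFINITE
                        err_t = (step + 1) * dt
                        err_comp = i
                        break
                    rec_all[rec_i, i] = v[i]
                if status != STATUS_OK:
                    break
            rec_i += 1

    return status, err_t, err_comp, rec_v, rec_ic, rec_all
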
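"""Implicit (backward-Euler) Hines solver for branched cable trees.

Internal unit system: mV, ms, nA, uS, nF.  The tree system is solved in
O(n) per step by symmetric elimination from the leaves to the root, which
is unconditionally stable for the passive + ohmic-tonic + gated-conductance
membrane used here (gates are updated by exact exponential relaxation using
the voltage at the start of the step, then the voltage equation — linear in
V for frozen gates — is solved implicitly).

Generic voltage-gated channels are described by up to two Boltzmann gates
with powers, a sigmoid steady state and a bell-shaped (or constant) time
constant; the hyperpolarization-activated current is expressed as two such
one-gate channels sharing an activation curve (fast and slow components).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _gate_inf(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


@njit(cache=True)
def _gate_tau(v, tau0, tau_amp, tau_vh, tau_k):
    if tau_amp == 0.0:
        return tau0
    e1 = np.exp((v - tau_vh) / tau_k)
    return tau0 + 2.0 * tau_amp / (e1 + 1.0 / e1)


@njit(cache=True)
def simulate_core(parent, gax, cap, gleak, eleak, gte, ete, gti, eti,
                  chan_gbar, chan_erev, chan_ngates, chan_gate_params,
                  gate_state,
                  syn_comp, syn_erev, syn_gpeak_norm, syn_ar, syn_ad,
                  ev_step, ev_syn, ev_weight,
                  stim_comp, stim_on, stim_off, stim_amp,
                  v0, dt, nsteps, probes, record_stride):
    """Integrate ``nsteps`` steps; return probe voltages.

    parent[0] must be -1 and parent[i] < i (topological order).
    gax[i] couples compartment i to its parent.  gleak/gte/gti are absolute
    conductances (uS); e* the reversal potentials (mV); cap in nF.
    """
    n = parent.shape[0]
    nchan = chan_gbar.shape[0]
    nsyn = syn_comp.shape[0]
    v = v0.copy()
    nrec = nsteps // record_stride + 1
    out = np.empty((probes.shape[0], nrec))
    for pi in range(probes.shape[0]):
        out[pi, 0] = v[probes[pi]]
    A = np.zeros(nsyn)
    B = np.zeros(nsyn)
    d = np.empty(n)
    b = np.empty(n)
    ev_i = 0
    nev = ev_step.shape[0]
    rec_i = 1
    for step in range(1, nsteps + 1):
        t0 = (step - 1) * dt
        # synaptic events scheduled in [t0, t0+dt)
        while ev_i < nev and ev_step[ev_i] < step:
            s = ev_syn[ev_i]
            A[s] += ev_weight[ev_i]
            B[s] += ev_weight[ev_i]
            ev_i += 1
        # gate update (exponential relaxation at frozen V)
        for c in range(nchan):
            for g in range(chan_ngates[c]):
                vh = chan_gate_params[c, g, 1]
                kk = chan_gate_params[c, g, 2]
                t0g = chan_gate_params[c, g, 3]
                ta = chan_gate_params[c, g, 4]
                tv = chan_gate_params[c, g, 5]
                tk = chan_gate_params[c, g, 6]
                for i in range(n):
                    minf = _gate_inf(v[i], vh, kk)
                    tau = _gate_tau(v[i], t0g, ta, tv, tk)
                    gate_state[c, g, i] = minf + (gate_state[c, g, i] - minf) \
                        * np.exp(-dt / tau)
        # assemble membrane conductance and rhs
        for i in range(n):
            gm = gleak[i] + gte[i] + gti[i]
            rhs = gleak[i] * eleak[i] + gte[i] * ete + gti[i] * eti
            d[i] = cap[i] / dt + gm
            b[i] = cap[i] / dt * v[i] + rhs
        for c in range(nchan):
            for i in range(n):
                go = chan_gbar[c, i]
                if go == 0.0:
                    continue
                for g in range(chan_ngates[c]):
                    p = chan_gate_params[c, g, 0]
                    s = gate_state[c, g, i]
                    if p == 1.0:
                        go *= s
                    else:
                        go *= s ** p
                d[i] += go
                b[i] += go * chan_erev[c]
        # synapses (decay analytically within the step midpoint)
        for s in range(nsyn):
            A[s] *= syn_ar[s]
            B[s] *= syn_ad[s]
            gs = syn_gpeak_norm[s] * (B[s] - A[s])
            if gs < 0.0:
                gs = 0.0
            i = syn_comp[s]
            d[i] += gs
            b[i] += gs * syn_erev[s]
        # current injections
        for q in range(stim_comp.shape[0]):
            if stim_on[q] <= t0 < stim_off[q]:
                b[stim_comp[q]] += stim_amp[q]
        # axial terms and Hines elimination
        for i in range(1, n):
            d[i] += gax[i]
            d[parent[i]] += gax[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / d[i]
            d[p] -= gax[i] * f
            b[p] += b[i] * f
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + gax[i] * v[parent[i]]) / d[i]
        if step % record_stride == 0:
            for pi in range(probes.shape[0]):
                out[pi, rec_i] = v[probes[pi]]
            rec_i += 1
        # NaN guard (cheap: check soma only)
        if not np.isfinite(v[0]):
            out[:, rec_i - 1] = np.nan
            return out
    return out
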
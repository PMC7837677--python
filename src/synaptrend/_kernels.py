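"""Compiled inner loop of the branched-cable integrator.

One Crank-Nicolson step solves the symmetric tree-tridiagonal system by
Hines elimination (children are ordered after their parents, so a single
backward sweep folds every branch onto the root in O(n)).  Synaptic
dual-exponential conductances are carried as per-compartment rise/decay
state pairs; Hodgkin-Huxley-type Na/K gates are advanced by exponential
integration between voltage solves.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _hh_rates(v):
    # classic squid-type rate constants expressed at a -65 mV resting frame
    if abs(v + 40.0) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * (v + 40.0) / (1.0 - math.exp(-(v + 40.0) / 10.0))
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    if abs(v + 55.0) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * (v + 55.0) / (1.0 - math.exp(-(v + 55.0) / 10.0))
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def integrate(parent, gax, cdt, gpas, el, gna, gk, ena, ek,
              n_steps, dt, v_init,
              ev_step, ev_comp, ev_w, f_rise, f_decay, e_syn,
              iinj, rec_idx, rec_start):
    """Integrate the cable for ``n_steps``; record from step ``rec_start``.

    Returns (recorded traces, final voltage).  ``ev_*`` arrays are sorted by
    step; ``f_rise``/``f_decay`` are per-step decay factors of the synaptic
    state pair; ``cdt`` is membrane capacitance divided by dt (nF/ms).
    """
    n = parent.shape[0]
    V = np.full(n, v_init)
    A = np.zeros(n)
    B = np.zeros(n)
    m = np.zeros(n)
    h = np.zeros(n)
    ng = np.zeros(n)
    for i in range(n):
        am, bm, ah, bh, an, bn = _hh_rates(V[i])
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        ng[i] = an / (an + bn)

    d = np.zeros(n)
    rhs = np.zeros(n)
    n_rec = rec_idx.shape[0]
    out = np.zeros((n_rec, n_steps - rec_start))

    ptr = 0
    n_ev = ev_step.shape[0]
    for step in range(n_steps):
        # synaptic state decay, then any event onsets at this step
        for i in range(n):
            A[i] *= f_rise
            B[i] *= f_decay
        while ptr < n_ev and ev_step[ptr] == step:
            c = ev_comp[ptr]
            A[c] += ev_w[ptr]
            B[c] += ev_w[ptr]
            ptr += 1

        # gates (exponential integration at the current voltage)
        for i in range(n):
            if gna[i] > 0.0 or gk[i] > 0.0:
                am, bm, ah, bh, an, bn = _hh_rates(V[i])
                tm = am + bm
                m[i] += (am / tm - m[i]) * (1.0 - math.exp(-dt * tm))
                th = ah + bh
                h[i] += (ah / th - h[i]) * (1.0 - math.exp(-dt * th))
                tn = an + bn
                ng[i] += (an / tn - ng[i]) * (1.0 - math.exp(-dt * tn))

        # assemble Crank-Nicolson system
        for i in range(n):
            gsyn = B[i] - A[i]
            gtot = gpas[i] + gsyn
            src = gpas[i] * el + gsyn * e_syn + iinj[i]
            if gna[i] > 0.0:
                gn = gna[i] * m[i] * m[i] * m[i] * h[i]
                gtot += gn
                src += gn * ena
            if gk[i] > 0.0:
                gkk = gk[i] * ng[i] * ng[i] * ng[i] * ng[i]
                gtot += gkk
                src += gkk * ek
            d[i] = cdt[i] + 0.5 * gtot
            rhs[i] = cdt[i] * V[i] - 0.5 * gtot * V[i] + src
        for i in range(1, n):
            g = gax[i]
            p = parent[i]
            d[i] += 0.5 * g
            d[p] += 0.5 * g
            rhs[i] -= 0.5 * g * (V[i] - V[p])
            rhs[p] -= 0.5 * g * (V[p] - V[i])

        # Hines elimination onto the root, then forward substitution
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = (-0.5 * gax[i]) / d[i]
            d[p] -= f * (-0.5 * gax[i])
            rhs[p] -= f * rhs[i]
        V[0] = rhs[0] / d[0]
        for i in range(1, n):
            V[i] = (rhs[i] + 0.5 * gax[i] * V[parent[i]]) / d[i]

        if step >= rec_start:
            for r in range(n_rec):
                out[r, step - rec_start] = V[rec_idx[r]]

    return out, V
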
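"""Numba inner loop for the coupled membrane/synapse integration.

All neurons advance synchronously on a shared fixed-step clock: at each step
every synapse reads its presynaptic voltage from the state at the start of
the step (one-step communication delay), gating variables take an
exponential update at frozen voltage, and V takes an explicit Euler step.
Reference semantics for the synapse pieces live in :mod:`wormbot.synapse`;
this module only restates them in a jit-compilable form.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# columns of the per-neuron parameter matrix
CM, GK, GNA, GCA, GL, VK, VNA, VL, VCA = range(9)
MCA_HALF, MCA_SLOPE, MCA_TAU, HCA_HALF, HCA_SLOPE, HCA_TAU = range(9, 15)
NPARAM = 15

STATUS_OK = 0
STATUS_BLOWUP = 1


@njit(cache=True)
def _rates_m(V):
    x = V + 40.0
    if abs(x) < 1e-7:
        a = 1.0  # L'Hopital limit of 0.1*x/(1-exp(-x/10))
    else:
        a = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    b = 4.0 * np.exp(-(V + 65.0) / 18.0)
    return a, b


@njit(cache=True)
def _rates_h(V):
    a = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return a, b


@njit(cache=True)
def _rates_n(V):
    x = V + 55.0
    if abs(x) < 1e-7:
        a = 0.1
    else:
        a = 0.01 * x / (1.0 - np.exp(-x / 10.0))
    b = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return a, b


@njit(cache=True)
def _ca_steady(V, half, slope, inact):
    # Boltzmann steady state; activation rises with V, inactivation falls
    if inact:
        return 1.0 / (1.0 + np.exp((V - half) / slope))
    return 1.0 / (1.0 + np.exp(-(V - half) / slope))


@njit(cache=True)
def run_kernel(
    V, m, n, h, mca, hca,            # per-neuron state, updated in place
    P,                               # (N, NPARAM) parameter matrix
    pre, post, g, e, w, dec, armed,  # per-synapse arrays; dec = exp(-dt/tau)
    syn_thr, syn_gain,
    stim_t, stim_amp, stim_on, stim_off,
    dt, nsteps, rec_idx, stride, out,
):
    """Advance the network ``nsteps`` steps, recording V for ``rec_idx``
    neurons every ``stride`` steps into ``out`` (column 0 = initial state).

    Returns (status, bad_step, bad_neuron); status 1 flags a non-finite V.
    """
    N = V.shape[0]
    S = pre.shape[0]
    R = rec_idx.shape[0]
    for r in range(R):
        out[r, 0] = V[rec_idx[r]]
    isyn = np.zeros(N)
    iext = np.zeros(N)
    for k in range(nsteps):
        t = k * dt
        # external stimulus
        for i in range(N):
            iext[i] = 0.0
        for p in range(stim_t.shape[0]):
            if stim_on[p] <= t < stim_off[p]:
                iext[stim_t[p]] += stim_amp[p]
        # chemical transmission: edge-triggered increment on upward
        # threshold crossing of the (previous-step) presynaptic voltage
        for s in range(S):
            vpre = V[pre[s]]
            if armed[s] == 1:
                if vpre >= syn_thr:
                    g[s] += w[s]
                    armed[s] = 0
            else:
                if vpre < syn_thr:
                    armed[s] = 1
        # postsynaptic currents, same sign convention as ionic currents
        for i in range(N):
            isyn[i] = 0.0
        for s in range(S):
            isyn[post[s]] += syn_gain * g[s] * (V[post[s]] - e[s])
        # membrane update
        for i in range(N):
            v = V[i]
            am, bm = _rates_m(v)
            ah, bh = _rates_h(v)
            an, bn = _rates_n(v)
            tm = 1.0 / (am + bm)
            th = 1.0 / (ah + bh)
            tn = 1.0 / (an + bn)
            m[i] = am * tm + (m[i] - am * tm) * np.exp(-dt / tm)
            h[i] = ah * th + (h[i] - ah * th) * np.exp(-dt / th)
            n[i] = an * tn + (n[i] - an * tn) * np.exp(-dt / tn)
            minf = _ca_steady(v, P[i, MCA_HALF], P[i, MCA_SLOPE], False)
            hinf = _ca_steady(v, P[i, HCA_HALF], P[i, HCA_SLOPE], True)
            mca[i] = minf + (mca[i] - minf) * np.exp(-dt / P[i, MCA_TAU])
            hca[i] = hinf + (hca[i] - hinf) * np.exp(-dt / P[i, HCA_TAU])
            ik = P[i, GK] * n[i] ** 4 * (v - P[i, VK])
            ina = P[i, GNA] * m[i] ** 3 * h[i] * (v - P[i, VNA])
            ica = P[i, GCA] * mca[i] ** 2 * hca[i] * (v - P[i, VCA])
            il = P[i, GL] * (v - P[i, VL])
            V[i] = v + dt * (iext[i] - ik - ina - ica - il - isyn[i]) / P[i, CM]
            if not np.isfinite(V[i]):
                return STATUS_BLOWUP, k, i
        # conductance decay (exact exponential)
        for s in range(S):
            g[s] *= dec[s]
        if (k + 1) % stride == 0:
            col = (k + 1) // stride
            if col < out.shape[1]:
                for r in range(R):
                    out[r, col] = V[rec_idx[r]]
    return STATUS_OK, -1, -1
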
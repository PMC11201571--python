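"""Independent reference implementations used as test oracles.

The monolithic integrator below restates the membrane/synapse equations
from the textbook forms and discretizes them differently from the engine
(forward Euler for every state, fully coupled same-step synaptic currents,
finer dt), so engine/oracle agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def hh_rates(V: float) -> tuple[float, float, float, float, float, float]:
    """Classical squid-axon alpha/beta for m, h, n (1/ms)."""
    x = V + 40.0
    am = 1.0 if abs(x) < 1e-7 else 0.1 * x / (1.0 - math.exp(-x / 10.0))
    bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    y = V + 55.0
    an = 0.1 if abs(y) < 1e-7 else 0.01 * y / (1.0 - math.exp(-y / 10.0))
    bn = 0.125 * math.exp(-(V + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def integrate_reference(
    params_list,
    synapses,
    stimuli,
    T: float,
    dt: float,
    syn_threshold: float = -30.0,
    syn_gain: float = 1.0,
    sample_every: int = 1,
):
    """Forward-Euler integration of the coupled membrane + synapse system.

    params_list: list of wormbot NeuronParams-like objects (attributes only).
    synapses: list of (pre, post, e, w, tau) index tuples.
    stimuli: list of (target_index, amplitude, t_on, t_off).
    Returns (times, V_samples[N, n_samples], gate_min, gate_max) where the
    gate extrema cover every integration step (for the [0, 1] invariant).
    """
    def steady_current(v, p):
        am, bm, ah, bh, an, bn = hh_rates(v)
        m0 = am / (am + bm)
        h0 = ah / (ah + bh)
        n0 = an / (an + bn)
        mca0 = 1.0 / (1.0 + math.exp(-(v - p.mca_half) / p.mca_slope))
        hca0 = 1.0 / (1.0 + math.exp((v - p.hca_half) / p.hca_slope))
        return (p.gK * n0**4 * (v - p.VK)
                + p.gNa * m0**3 * h0 * (v - p.VNa)
                + p.gCa * mca0**2 * hca0 * (v - p.VCa)
                + p.gl * (v - p.Vl))

    def rest(p):
        # lowest zero of the steady-state I-V curve, by scan + bisection
        vs = np.linspace(min(p.VK, p.Vl) - 20.0, 0.0, 2001)
        cur = [steady_current(v, p) for v in vs]
        for a, b, ca, cb in zip(vs, vs[1:], cur, cur[1:]):
            if (ca < 0.0) != (cb < 0.0):
                for _ in range(80):
                    mid = 0.5 * (a + b)
                    if (steady_current(a, p) < 0.0) == (steady_current(mid, p) < 0.0):
                        a = mid
                    else:
                        b = mid
                return 0.5 * (a + b)
        raise ValueError("no rest found")

    N = len(params_list)
    V = np.array([rest(p) for p in params_list], dtype=float)
    m = np.empty(N)
    n = np.empty(N)
    h = np.empty(N)
    mca = np.empty(N)
    hca = np.empty(N)
    for i, p in enumerate(params_list):
        am, bm, ah, bh, an, bn = hh_rates(V[i])
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        n[i] = an / (an + bn)
        mca[i] = 1.0 / (1.0 + math.exp(-(V[i] - p.mca_half) / p.mca_slope))
        hca[i] = 1.0 / (1.0 + math.exp((V[i] - p.hca_half) / p.hca_slope))
    g = np.zeros(len(synapses))
    armed = np.ones(len(synapses), dtype=bool)
    nsteps = int(round(T / dt))
    times = [0.0]
    samples = [V.copy()]
    gate_min, gate_max = 1.0, 0.0
    for k in range(nsteps):
        t = k * dt
        iext = np.zeros(N)
        for tgt, amp, t_on, t_off in stimuli:
            if t_on <= t < t_off:
                iext[tgt] += amp
        isyn = np.zeros(N)
        for s, (pre, post, e, w, tau) in enumerate(synapses):
            if armed[s] and V[pre] >= syn_threshold:
                g[s] += w
                armed[s] = False
            elif V[pre] < syn_threshold:
                armed[s] = True
            isyn[post] += syn_gain * g[s] * (V[post] - e)
        dV = np.empty(N)
        for i, p in enumerate(params_list):
            am, bm, ah, bh, an, bn = hh_rates(V[i])
            minf = 1.0 / (1.0 + math.exp(-(V[i] - p.mca_half) / p.mca_slope))
            hinf = 1.0 / (1.0 + math.exp((V[i] - p.hca_half) / p.hca_slope))
            dm = am * (1.0 - m[i]) - bm * m[i]
            dh = ah * (1.0 - h[i]) - bh * h[i]
            dn = an * (1.0 - n[i]) - bn * n[i]
            dmca = (minf - mca[i]) / p.mca_tau
            dhca = (hinf - hca[i]) / p.hca_tau
            ik = p.gK * n[i] ** 4 * (V[i] - p.VK)
            ina = p.gNa * m[i] ** 3 * h[i] * (V[i] - p.VNa)
            ica = p.gCa * mca[i] ** 2 * hca[i] * (V[i] - p.VCa)
            il = p.gl * (V[i] - p.Vl)
            dV[i] = (iext[i] - ik - ina - ica - il - isyn[i]) / p.Cm
            m[i] += dt * dm
            h[i] += dt * dh
            n[i] += dt * dn
            mca[i] += dt * dmca
            hca[i] += dt * dhca
        V += dt * dV
        for s in range(len(synapses)):
            g[s] *= math.exp(-dt / synapses[s][4])
        gate_min = min(gate_min, m.min(), n.min(), h.min(), mca.min(), hca.min())
        gate_max = max(gate_max, m.max(), n.max(), h.max(), mca.max(), hca.max())
        if (k + 1) % sample_every == 0:
            times.append((k + 1) * dt)
            samples.append(V.copy())
    return np.array(times), np.array(samples).T, gate_min, gate_max


def axis_angle_quaternion(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[math.cos(angle / 2.0)],
                           math.sin(angle / 2.0) * axis])
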
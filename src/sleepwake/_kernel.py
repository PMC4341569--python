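"""Numba inner loop for the conductance-based network integrator.

The integrator advances a single-compartment Hodgkin–Huxley population
network with difference-of-exponentials synapses, spike-triggered AHP
adaptation, white current noise, square-pulse/constant injected currents,
a first-order neocortical rate unit, and the two feedback paths
(neocortex→Hcrt state feedback, wake-event→neocortex output feedback).

Gating-variable kinetics are tabulated on a fine voltage grid so the hot
loop performs no transcendental calls besides the membrane update and the
noise draw.  All state arrays are updated in place; the caller drives the
kernel in fixed 100-ms chunks and reseeds the RNG per chunk so that a trial
is reproducible regardless of how the chunks are scheduled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# voltage grid for the kinetics tables
V_TAB_LO = -120.0
V_TAB_HI = 60.0
V_TAB_STEP = 0.05
V_TAB_N = int(round((V_TAB_HI - V_TAB_LO) / V_TAB_STEP)) + 1

_table_cache: dict = {}


def _safe_exprel(x: np.ndarray) -> np.ndarray:
    # x / (1 - exp(-x)) with the x -> 0 limit handled
    out = np.empty_like(x)
    small = np.abs(x) < 1e-7
    out[small] = 1.0
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-xs))
    return out


def gate_tables(dt: float):
    """Tabulated steady states and exponential-Euler decay factors.

    Returns (minf, em, hinf, eh, ninf, en), each of length ``V_TAB_N``,
    for the classic squid-style kinetics used by every population.
    """
    key = round(dt, 9)
    if key in _table_cache:
        return _table_cache[key]
    v = V_TAB_LO + V_TAB_STEP * np.arange(V_TAB_N)

    # alpha_m = 0.1 (V+40) / (1 - exp(-(V+40)/10)) = exprel((V+40)/10), etc.
    am = _safe_exprel((v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _safe_exprel((v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)

    minf = am / (am + bm)
    hinf = ah / (ah + bh)
    ninf = an / (an + bn)
    em = np.exp(-dt * (am + bm))
    eh = np.exp(-dt * (ah + bh))
    en = np.exp(-dt * (an + bn))
    tabs = (minf, em, hinf, eh, ninf, en)
    _table_cache[key] = tabs
    return tabs


@njit(cache=True)
def integrate_chunk(
    # mutable state
    V, m, h, n, gahp,            # (N,)
    A, B,                        # (P, N) two-filter synaptic states
    ring,                        # (ring_len, N) uint8 spike flags
    pop_rate_est,                # (K,) Hz, online exponential estimate
    nc_state,                    # (1,) neocortical rate unit (Hz)
    last_spike,                  # (N,) int64, global step of last spike
    # outputs
    sp_t, sp_i,                  # spike buffers
    v_rec,                       # (n_rows, N) voltage recording
    # schedule
    step0, n_steps, dt, rec_stride,
    # per-neuron parameters
    Cm, gNa, gK, gL, ENa, EK, EL, Vth, sigma, dg_ahp, ahp_decay, Idrive,
    pop_of, pop_size,
    # projections
    W, decA, decB, Erev, delay_steps, norm,
    # kinetics tables
    minf_t, em_t, hinf_t, eh_t, ninf_t, en_t,
    # protocol currents
    prot_pop, prot_mode, prot_on, prot_off, prot_period, prot_width, prot_amp,
    # neocortex unit + feedback
    has_nc, nc_tau, nc_w, fb_out_gain, fb_state_gain, fb_target_pop,
    arous_pop, wake_thresh,
    # misc
    rate_decay, rate_tau, refr_steps, seed,
):
    np.random.seed(seed)
    N = V.shape[0]
    P = W.shape[0]
    K = pop_size.shape[0]
    S = prot_pop.shape[0]
    ring_len = ring.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    n_spikes = 0
    cap = sp_t.shape[0]

    pop_amp = np.zeros(K)
    gsum = np.zeros(N)
    gEsum = np.zeros(N)

    for s in range(n_steps):
        gstep = step0 + s
        t = gstep * dt
        cur_slot = gstep % ring_len
        for i in range(N):
            ring[cur_slot, i] = 0

        # injected protocol current per population
        for k in range(K):
            pop_amp[k] = 0.0
        for q in range(S):
            if prot_on[q] <= t < prot_off[q]:
                if prot_mode[q] == 1:
                    if prot_period[q] > 0.0:
                        phase = (t - prot_on[q]) % prot_period[q]
                        if phase < prot_width[q]:
                            pop_amp[prot_pop[q]] += prot_amp[q]
                    else:
                        pop_amp[prot_pop[q]] += prot_amp[q]
                else:
                    pop_amp[prot_pop[q]] -= prot_amp[q]

        # synaptic filters: decay, then delayed spike propagation
        for p in range(P):
            da = decA[p]
            db = decB[p]
            for i in range(N):
                A[p, i] *= da
                B[p, i] *= db
        for p in range(P):
            slot = (gstep - delay_steps[p]) % ring_len
            for j in range(N):
                if ring[slot, j] == 1:
                    for i in range(N):
                        w = W[p, i, j]
                        if w != 0.0:
                            A[p, i] += w
                            B[p, i] += w

        # total synaptic conductance per neuron
        for i in range(N):
            gsum[i] = 0.0
            gEsum[i] = 0.0
        for p in range(P):
            np_ = norm[p]
            ep = Erev[p]
            for i in range(N):
                g = np_ * (A[p, i] - B[p, i])
                if g > 0.0:
                    gsum[i] += g
                    gEsum[i] += g * ep

        nc_now = nc_state[0]

        for i in range(N):
            v_old = V[i]
            # table lookup for gate kinetics
            idx = int((v_old - V_TAB_LO) * 20.0 + 0.5)
            if idx < 0:
                idx = 0
            elif idx >= V_TAB_N:
                idx = V_TAB_N - 1

            gna = gNa[i] * m[i] * m[i] * m[i] * h[i]
            gk = gK[i] * n[i] * n[i] * n[i] * n[i]
            gtot = gL[i] + gna + gk + gahp[i] + gsum[i]
            Iext = Idrive[i] + pop_amp[pop_of[i]]
            if fb_target_pop >= 0 and pop_of[i] == fb_target_pop:
                Iext += fb_state_gain * nc_now
            if sigma[i] > 0.0:
                Iext += sigma[i] * inv_sqrt_dt * np.random.standard_normal()
            gE = (
                gL[i] * EL[i]
                + gna * ENa[i]
                + gk * EK[i]
                + gahp[i] * EK[i]
                + gEsum[i]
            )
            vinf = (gE + Iext) / gtot
            v_new = vinf + (v_old - vinf) * np.exp(-dt * gtot / Cm[i])

            m[i] = minf_t[idx] + (m[i] - minf_t[idx]) * em_t[idx]
            h[i] = hinf_t[idx] + (h[i] - hinf_t[idx]) * eh_t[idx]
            n[i] = ninf_t[idx] + (n[i] - ninf_t[idx]) * en_t[idx]
            gahp[i] *= ahp_decay[i]

            if v_new > 150.0 or v_new < -150.0:
                return n_spikes, i, gstep

            if v_old < Vth[i] and v_new >= Vth[i]:
                if gstep - last_spike[i] >= refr_steps:
                    last_spike[i] = gstep
                    ring[cur_slot, i] = 1
                    gahp[i] += dg_ahp[i]
                    k = pop_of[i]
                    pop_rate_est[k] += 1000.0 / (rate_tau * pop_size[k])
                    if n_spikes < cap:
                        sp_t[n_spikes] = t
                        sp_i[n_spikes] = i
                        n_spikes += 1
            V[i] = v_new

        for k in range(K):
            pop_rate_est[k] *= rate_decay

        if has_nc == 1:
            drive = 0.0
            for k in range(K):
                drive += nc_w[k] * pop_rate_est[k]
            arous = nc_now if arous_pop < 0 else pop_rate_est[arous_pop]
            if arous > wake_thresh:
                drive += fb_out_gain
            nc_state[0] = nc_now + dt / nc_tau * (drive - nc_now)

        if gstep % rec_stride == 0:
            row = gstep // rec_stride
            if row < v_rec.shape[0]:
                for i in range(N):
                    v_rec[row, i] = V[i]

    return n_spikes, -1, -1
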
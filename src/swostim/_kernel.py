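"""Vectorized network integration kernel (numba).

Re-implements the scalar update rules of :mod:`swostim.dynamics` and
:mod:`swostim.plasticity` for the whole lattice in one compiled loop.
Equivalence with the scalar reference is covered by tests.

Integration scheme: forward Euler on the Izhikevich voltage equation with
two half-steps per dt (0.25 ms halves at the default 0.5 ms), one Euler step
per dt for the recovery variable, exact exponential decay for conductances.
Per-step white-noise current (held constant over the step) provides the
small perturbations that seed DOWN->UP transitions and the irregular cycle
timing of human slow waves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SPIKE_THRESHOLD = 30.0


@njit(cache=True)
def run_network(
    n_steps,
    dt_ms,
    # neuron parameters
    a,
    b,
    c,
    d,
    e_ss,
    k_e,
    tau_r_s,
    is_exc,
    # synaptic kinetics
    dec_ampa,
    dec_nmda,
    dec_gabaa,
    dec_gabab,
    E_exc,
    E_gabaa,
    E_gabab,
    # connectivity (CSR over presynaptic neurons -> outgoing edges)
    exc_indptr,
    exc_targets,
    exc_weights,
    inh_indptr,
    inh_targets,
    inh_weights,
    nmda_frac,
    gabab_frac,
    # stimulation: per-neuron current at unit envelope, and envelope series
    field_drive,
    envelope,
    # noise
    noise_std,
    seed,
    # plasticity
    plasticity_on,
    r0,
    tau_h_s,
    stale_after_s,
    relative_error,
    w_hom0,
    # recording
    region_id,
    n_regions,
    rec_stride,
    max_spikes,
    # initial state
    v0,
    u0,
    r_leaky0,
):
    n = a.shape[0]
    dt_s = dt_ms * 1e-3
    np.random.seed(seed)

    v = v0.copy()
    u = u0.copy()
    r = r_leaky0.copy()  # leaky rate estimate for the excitability feedback
    g_ampa = np.zeros(n)
    g_nmda = np.zeros(n)
    g_gabaa = np.zeros(n)
    g_gabab = np.zeros(n)
    w_hom = w_hom0.copy()
    r_inst = np.zeros(n)
    last_spike = np.full(n, -np.inf)

    r_decay = np.exp(-dt_s / tau_r_s)
    r_kick = 1.0 / tau_r_s

    lfp = np.zeros(n_steps)
    region_lfp = np.zeros((n_regions, n_steps))
    region_count = np.zeros(n_regions)
    for i in range(n):
        if region_id[i] >= 0:
            region_count[region_id[i]] += 1.0

    n_rec = (n_steps + rec_stride - 1) // rec_stride
    w_hom_mean = np.zeros(n_rec)
    r_inst_mean = np.zeros(n_rec)

    spike_neuron = np.empty(max_spikes, dtype=np.int32)
    spike_step = np.empty(max_spikes, dtype=np.int32)
    n_spikes = 0
    overflow = False

    half = dt_ms * 0.5

    for s in range(n_steps):
        t = s * dt_s
        env = envelope[s]

        # conductance decay
        for i in range(n):
            g_ampa[i] *= dec_ampa
            g_nmda[i] *= dec_nmda
            g_gabaa[i] *= dec_gabaa
            g_gabab[i] *= dec_gabab

        # synaptic currents, LFP, total drive, voltage update
        lfp_acc = 0.0
        step_start = n_spikes
        for i in range(n):
            vi = v[i]
            x = (vi + 80.0) / 60.0
            bnmda = x * x / (1.0 + x * x)
            i_syn = w_hom[i] * (g_ampa[i] + g_nmda[i] * bnmda) * (E_exc - vi)
            i_syn += g_gabaa[i] * (E_gabaa - vi) + g_gabab[i] * (E_gabab - vi)
            lfp_acc += i_syn
            if region_id[i] >= 0:
                region_lfp[region_id[i], s] += i_syn

            e_bias = e_ss[i] - k_e * r[i]
            drive = (
                i_syn
                + e_bias
                + field_drive[i] * env
                + noise_std * np.random.normal(0.0, 1.0)
            )

            vi = vi + half * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + drive)
            spiked = vi >= SPIKE_THRESHOLD
            if not spiked:
                if vi < -120.0:  # numerical guard against Euler undershoot
                    vi = -120.0
                vi = vi + half * (0.04 * vi * vi + 5.0 * vi + 140.0 - u[i] + drive)
                spiked = vi >= SPIKE_THRESHOLD
            if spiked:
                # clamp spike-time voltage so the u-update stays bounded
                vi = SPIKE_THRESHOLD
            elif vi < -120.0:
                vi = -120.0
            u[i] = u[i] + dt_ms * a[i] * (b[i] * vi - u[i])
            r[i] *= r_decay
            if spiked:
                vi = c[i]
                u[i] += d[i]
                r[i] += r_kick
                t_spike = t + dt_s
                if last_spike[i] > -1e300:
                    r_inst[i] = 1.0 / (t_spike - last_spike[i])
                last_spike[i] = t_spike
                if n_spikes < max_spikes:
                    spike_neuron[n_spikes] = i
                    spike_step[n_spikes] = s
                    n_spikes += 1
                else:
                    overflow = True
            v[i] = vi

        # deliver this step's spikes to postsynaptic conductances at the end
        # of the step (one-step synaptic latency keeps avalanches causal)
        for m in range(step_start, n_spikes):
            i = spike_neuron[m]
            if is_exc[i]:
                for k in range(exc_indptr[i], exc_indptr[i + 1]):
                    j = exc_targets[k]
                    g_ampa[j] += exc_weights[k]
                    g_nmda[j] += exc_weights[k] * nmda_frac
            else:
                for k in range(inh_indptr[i], inh_indptr[i + 1]):
                    j = inh_targets[k]
                    g_gabaa[j] += inh_weights[k]
                    g_gabab[j] += inh_weights[k] * gabab_frac

        lfp[s] = lfp_acc / n
        for q in range(n_regions):
            region_lfp[q, s] /= region_count[q]

        # staleness applies to the rate estimate itself, plasticity or not:
        # a neuron silent beyond the horizon reads as rate zero
        for i in range(n):
            if t - last_spike[i] > stale_after_s:
                r_inst[i] = 0.0

        if plasticity_on:
            for i in range(n):
                err = r0 - r_inst[i]
                if relative_error:
                    err /= r0
                w_hom[i] += (dt_s / tau_h_s) * err
                if w_hom[i] < 0.0:
                    w_hom[i] = 0.0

        if s % rec_stride == 0:
            idx = s // rec_stride
            wm = 0.0
            rm = 0.0
            for i in range(n):
                wm += w_hom[i]
                rm += r_inst[i]
            w_hom_mean[idx] = wm / n
            r_inst_mean[idx] = rm / n

    return (
        lfp,
        region_lfp,
        spike_neuron[:n_spikes],
        spike_step[:n_spikes],
        overflow,
        w_hom_mean,
        r_inst_mean,
        v,
        u,
        r,
        w_hom,
    )


def out_csr(edges: np.ndarray, weights: np.ndarray, n: int):
    """Group edges by presynaptic neuron into CSR arrays (indptr, targets, w)."""
    order = np.argsort(edges[:, 0], kind="stable")
    pre = edges[order, 0]
    targets = edges[order, 1].astype(np.int64)
    w = weights[order].astype(np.float64)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, targets, w
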
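"""Numba inner loops for the Euler integration of the membrane dynamics.

Both kernels integrate

    tau_mem dV_i/dt = -(V_i - V_R) + synaptic delta inputs,

with every presynaptic spike depolarizing its target instantaneously by the
coupling strength (J_ext, J_exc or -J_inh).  ``run_full`` delivers recurrent
spikes at the next integration step; ``run_avalanche`` delivers them
instantaneously within the step, resolving complete cascades
generation-by-generation (separation of timescales).

Connectivity is passed in compressed form: ``out_indptr``/``out_indices``
list, for every presynaptic neuron j, the postsynaptic targets i with
w[i, j] = 1.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_full", "run_avalanche", "poisson_counts"]


@njit(cache=True)
def _splitmix64(state):
    """One step of the splitmix64 generator; returns (new_state, uniform)."""
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, (z >> np.uint64(11)) * 1.1102230246251565e-16  # 2^-53


@njit(cache=True)
def poisson_counts(n_steps, n_driven, cdf, seed):
    """Matrix of iid Poisson counts via inverse-CDF lookup.

    ``cdf`` is the tabulated Poisson CDF (cut where the tail is < 1e-12);
    uniforms come from a splitmix64 counter RNG seeded with ``seed`` (two
    24-bit uniforms per 64-bit word; the 6e-8 quantile granularity is far
    below any statistic resolved here), so equal seeds give identical
    input realizations.
    """
    n = n_steps * n_driven
    out = np.empty(n, np.uint8)
    state = np.uint64(seed)
    kmax = cdf.size - 1
    scale = 1.0 / (1 << 24)
    i = 0
    while i < n:
        state = state + np.uint64(0x9E3779B97F4A7C15)
        z = state
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
        u = np.float64(z >> np.uint64(40)) * scale
        k = 0
        while k < kmax and u > cdf[k]:
            k += 1
        out[i] = k
        i += 1
        if i < n:
            u = np.float64(z & np.uint64(0xFFFFFF)) * scale
            k = 0
            while k < kmax and u > cdf[k]:
                k += 1
            out[i] = k
            i += 1
    return out.reshape(n_steps, n_driven)


@njit(cache=True)
def _grow(arr, n):  # pragma: no cover - trivial buffer doubling
    out = np.empty(max(2 * arr.size, n), arr.dtype)
    out[: arr.size] = arr
    return out


@njit(cache=True)
def run_full(
    v,
    out_indptr,
    out_indices,
    n_exc,
    j_exc,
    j_inh,
    j_ext,
    leak,
    v_rest,
    v_theta,
    ext_counts,
    driven,
):
    """Integrate the full model; recurrent spikes arrive one step later.

    Parameters
    ----------
    v : float64[N]
        Initial membrane potentials, modified in place.
    ext_counts : uint8[n_steps, n_driven]
        External Poisson spike counts per step for each driven neuron.
    driven : int64[n_driven]
        Indices of the externally driven neurons.

    Returns
    -------
    spike_step, spike_id : int64 arrays of recurrent-layer spikes
    ext_total : int64[n_steps] external spikes delivered per step
    err_step : -1, or the first step at which a potential went non-finite
    """
    n = v.size
    n_steps = ext_counts.shape[0]
    n_driven = driven.size
    inbuf = np.zeros(n, np.float64)
    fired = np.empty(n, np.int64)
    cap = 65536
    spike_step = np.empty(cap, np.int64)
    spike_id = np.empty(cap, np.int64)
    nsp = 0
    ext_total = np.zeros(n_steps, np.int64)
    for t in range(n_steps):
        tot = 0
        for d in range(n_driven):
            c = ext_counts[t, d]
            if c > 0:
                inbuf[driven[d]] += j_ext * c
                tot += c
        ext_total[t] = tot
        nf = 0
        ok = True
        for i in range(n):
            vi = v[i] + leak * (v_rest - v[i]) + inbuf[i]
            inbuf[i] = 0.0
            if not np.isfinite(vi):
                ok = False
            if vi >= v_theta:
                fired[nf] = i
                nf += 1
                vi = v_rest
            v[i] = vi
        if not ok:
            return spike_step[:nsp], spike_id[:nsp], ext_total, t
        if nf > 0:
            if nsp + nf > cap:
                spike_step = _grow(spike_step, nsp + nf)
                spike_id = _grow(spike_id, nsp + nf)
                cap = spike_step.size
            for k in range(nf):
                j = fired[k]
                spike_step[nsp] = t
                spike_id[nsp] = j
                nsp += 1
                amp = j_exc if j < n_exc else -j_inh
                for idx in range(out_indptr[j], out_indptr[j + 1]):
                    inbuf[out_indices[idx]] += amp
    return spike_step[:nsp], spike_id[:nsp], ext_total, -1


@njit(cache=True)
def run_avalanche(
    v,
    out_indptr,
    out_indices,
    n_exc,
    j_exc,
    j_inh,
    j_ext,
    leak,
    v_rest,
    v_theta,
    ext_counts,
    driven,
):
    """Integrate the reduced model with instantaneous cascade propagation.

    Any threshold crossing within a step starts an avalanche: all crossing
    neurons form generation 1, their spikes are delivered instantaneously,
    newly crossing neurons form the next generation, and so on until no new
    neuron crosses.  A neuron fires at most once per cascade and is held at
    V_R for the remainder of the cascade (no further input delivery).

    Returns
    -------
    spike_step, spike_id : int64 arrays (all cascade spikes share the step)
    ext_total : int64[n_steps]
    av_step, av_size, av_dur : int64 arrays, one entry per avalanche
    err_step : -1, or first step with a non-finite potential
    """
    n = v.size
    n_steps = ext_counts.shape[0]
    n_driven = driven.size
    in_cascade = np.zeros(n, np.uint8)
    frontier = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    cap = 65536
    spike_step = np.empty(cap, np.int64)
    spike_id = np.empty(cap, np.int64)
    nsp = 0
    acap = 16384
    av_step = np.empty(acap, np.int64)
    av_size = np.empty(acap, np.int64)
    av_dur = np.empty(acap, np.int64)
    nav = 0
    ext_total = np.zeros(n_steps, np.int64)
    for t in range(n_steps):
        tot = 0
        ok = True
        for i in range(n):
            v[i] += leak * (v_rest - v[i])
        for d in range(n_driven):
            c = ext_counts[t, d]
            if c > 0:
                v[driven[d]] += j_ext * c
                tot += c
        ext_total[t] = tot
        nf = 0
        for i in range(n):
            if not np.isfinite(v[i]):
                ok = False
            if v[i] >= v_theta:
                frontier[nf] = i
                nf += 1
        if not ok:
            return (
                spike_step[:nsp],
                spike_id[:nsp],
                ext_total,
                av_step[:nav],
                av_size[:nav],
                av_dur[:nav],
                t,
            )
        if nf == 0:
            continue
        size = 0
        gens = 0
        first_spike = nsp
        while nf > 0:
            gens += 1
            # refractoriness guarantees termination within n generations
            assert gens <= n
            if nsp + nf > cap:
                spike_step = _grow(spike_step, nsp + nf)
                spike_id = _grow(spike_id, nsp + nf)
                cap = spike_step.size
            for k in range(nf):
                i = frontier[k]
                in_cascade[i] = 1
                v[i] = v_rest
                spike_step[nsp] = t
                spike_id[nsp] = i
                nsp += 1
                size += 1
            for k in range(nf):
                j = frontier[k]
                amp = j_exc if j < n_exc else -j_inh
                for idx in range(out_indptr[j], out_indptr[j + 1]):
                    tgt = out_indices[idx]
                    if in_cascade[tgt] == 0:
                        v[tgt] += amp
            nf2 = 0
            for i in range(n):
                if in_cascade[i] == 0 and v[i] >= v_theta:
                    nxt[nf2] = i
                    nf2 += 1
            for k in range(nf2):
                frontier[k] = nxt[k]
            nf = nf2
        for k in range(first_spike, nsp):
            in_cascade[spike_id[k]] = 0
        if nav >= acap:
            av_step = _grow(av_step, nav + 1)
            av_size = _grow(av_size, nav + 1)
            av_dur = _grow(av_dur, nav + 1)
            acap = av_step.size
        av_step[nav] = t
        av_size[nav] = size
        av_dur[nav] = gens
        nav += 1
    return (
        spike_step[:nsp],
        spike_id[:nsp],
        ext_total,
        av_step[:nav],
        av_size[:nav],
        av_dur[:nav],
        -1,
    )
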
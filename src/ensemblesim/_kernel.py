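"""Inner integration kernel.

The simulation advances in chunks of a few hundred steps.  Per chunk, the
noise increments and Poisson background events are pre-drawn with the seeded
numpy Generator (so reproducibility is owned by numpy, not the kernel), and a
tight loop advances membrane voltages, conductances, delay ring buffers,
spikes, voltage traces, and windowed voltage accumulators.  The loop is
compiled with numba when available; a pure-numpy twin with identical
semantics serves as fallback.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def run_chunk(t0, n_sub, v, g_e, g_i, eta, refr_left,
              buf_e, buf_i,
              v_leak, b_pa, poisson_jump,
              noise_chunk, noise_a, noise_every,
              ev_step, ev_neuron,
              active_chunk, set_offsets, set_data,
              indptr, indices, wdata, delay_steps, pre_exc,
              decay_e, decay_i, g_l, inv_cm,
              v_exc, v_inh, v_thresh, v_reset, refr_steps,
              g_ops, v_ops,
              spike_step, spike_id,
              rec_ids, rec_every, traces,
              win_chunk, window_ids, wsums, wcounts):
    n = v.shape[0]
    D = buf_e.shape[0]
    dv = np.empty(n)
    n_spikes = 0
    ev_ptr = 0
    n_events = ev_step.shape[0]
    rec_n = rec_ids.shape[0]
    win_n = window_ids.shape[0]
    for k in range(n_sub):
        t = t0 + k
        slot = t % D
        for j in range(n):
            g_e[j] = g_e[j] * decay_e + buf_e[slot, j]
            g_i[j] = g_i[j] * decay_i + buf_i[slot, j]
            buf_e[slot, j] = 0.0
            buf_i[slot, j] = 0.0
        if t % noise_every == 0:
            row = k // noise_every
            for j in range(n):
                eta[j] = eta[j] * noise_a + noise_chunk[row, j]
        while ev_ptr < n_events and ev_step[ev_ptr] == k:
            g_e[ev_neuron[ev_ptr]] += poisson_jump[ev_neuron[ev_ptr]]
            ev_ptr += 1
        for j in range(n):
            dv[j] = (-g_l * (v[j] - v_leak[j]) - g_e[j] * (v[j] - v_exc)
                     - g_i[j] * (v[j] - v_inh) + b_pa[j] + g_l * eta[j]) * inv_cm
        sid = active_chunk[k]
        if sid >= 0:
            for m in range(set_offsets[sid], set_offsets[sid + 1]):
                idx = set_data[m]
                dv[idx] += -g_ops * (v[idx] - v_ops) * inv_cm
        for j in range(n):
            if refr_left[j] > 0:
                v[j] = v_reset
                refr_left[j] -= 1
                continue
            v[j] += dv[j]
            if v[j] >= v_thresh:
                spike_step[n_spikes] = t
                spike_id[n_spikes] = j
                n_spikes += 1
                v[j] = v_reset
                refr_left[j] = refr_steps
                for s in range(indptr[j], indptr[j + 1]):
                    arr_slot = (t + delay_steps[s]) % D
                    if pre_exc[j]:
                        buf_e[arr_slot, indices[s]] += wdata[s]
                    else:
                        buf_i[arr_slot, indices[s]] += wdata[s]
        if rec_n > 0 and t % rec_every == 0:
            col = t // rec_every
            for r in range(rec_n):
                traces[r, col] = v[rec_ids[r]]
        wi = win_chunk[k]
        if wi >= 0:
            for m in range(win_n):
                wsums[wi, m] += v[window_ids[m]]
            wcounts[wi] += 1
    return n_spikes


def run_chunk_numpy(t0, n_sub, v, g_e, g_i, eta, refr_left,
                    buf_e, buf_i,
                    v_leak, b_pa, poisson_jump,
                    noise_chunk, noise_a, noise_every,
                    ev_step, ev_neuron,
                    active_chunk, set_offsets, set_data,
                    indptr, indices, wdata, delay_steps, pre_exc,
                    decay_e, decay_i, g_l, inv_cm,
                    v_exc, v_inh, v_thresh, v_reset, refr_steps,
                    g_ops, v_ops,
                    spike_step, spike_id,
                    rec_ids, rec_every, traces,
                    win_chunk, window_ids, wsums, wcounts):
    """Vectorized twin of :func:`run_chunk` (same state updates per step)."""
    D = buf_e.shape[0]
    n_spikes = 0
    ev_ptr = 0
    n_events = len(ev_step)
    for k in range(n_sub):
        t = t0 + k
        slot = t % D
        g_e *= decay_e
        g_i *= decay_i
        g_e += buf_e[slot]
        g_i += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0
        if t % noise_every == 0:
            eta *= noise_a
            eta += noise_chunk[k // noise_every]
        while ev_ptr < n_events and ev_step[ev_ptr] == k:
            g_e[ev_neuron[ev_ptr]] += poisson_jump[ev_neuron[ev_ptr]]
            ev_ptr += 1
        dv = (-g_l * (v - v_leak) - g_e * (v - v_exc) - g_i * (v - v_inh)
              + b_pa + g_l * eta) * inv_cm
        sid = active_chunk[k]
        if sid >= 0:
            tgt = set_data[set_offsets[sid]:set_offsets[sid + 1]]
            dv[tgt] += -g_ops * (v[tgt] - v_ops) * inv_cm
        refr = refr_left > 0
        v += dv
        v[refr] = v_reset
        refr_left[refr] -= 1
        spiking = np.flatnonzero((v >= v_thresh) & ~refr)
        for j in spiking:
            spike_step[n_spikes] = t
            spike_id[n_spikes] = j
            n_spikes += 1
            v[j] = v_reset
            refr_left[j] = refr_steps
            lo, hi = indptr[j], indptr[j + 1]
            if lo == hi:
                continue
            buf = buf_e if pre_exc[j] else buf_i
            np.add.at(buf, ((t + delay_steps[lo:hi]) % D, indices[lo:hi]), wdata[lo:hi])
        if len(rec_ids) > 0 and t % rec_every == 0:
            traces[:, t // rec_every] = v[rec_ids]
        wi = win_chunk[k]
        if wi >= 0:
            wsums[wi] += v[window_ids]
            wcounts[wi] += 1
    return n_spikes
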
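"""Independent reference integrator for cross-checking the engine.

Deliberately naive: scalar per-neuron updates at a fine step (default
1 us), explicit per-step event bookkeeping, and no code shared with
``connlif.engine``. Each step applies the closed-form solution of the two
linear ODEs (v relaxing toward V_rest + g, g decaying exponentially), so
the comparison isolates the engine's coarse-grid event handling — delays,
refractory clamping, threshold detection and vectorized bookkeeping —
rather than integrator truncation error. Spike semantics follow the same
model contract: spike on v >= V_threshold (closed boundary), v <- V_reset
and g <- 0 on own spike, membrane clamped and threshold suspended during
the refractory period while g keeps decaying and accumulating, and
increments delivered T_dly after each spike.
"""

from __future__ import annotations

import numpy as np


def reference_simulate(triplets, neuron_ids, params, forced_times,
                       duration_ms, dt=0.001):
    """Simulate with forward-Euler; return {neuron_id: [spike times]}.

    triplets: iterable of (pre_id, post_id, weight_mv).
    forced_times: {neuron_id: iterable of forced spike times (ms)}.
    """
    ids = list(neuron_ids)
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    out_edges = [[] for _ in range(n)]
    for pre, post, wmv in triplets:
        out_edges[idx[pre]].append((idx[post], float(wmv)))

    n_steps = int(round(duration_ms / dt))
    d_steps = int(round(params.t_dly / dt))
    v = [params.v_resting] * n
    g = [0.0] * n
    refr_until = [-1e18] * n
    a = 1.0 / params.t_mbr
    b = 1.0 / params.tau if np.isfinite(params.tau) else 0.0
    decay_v = float(np.exp(-a * dt))
    decay_g = float(np.exp(-b * dt))
    # closed-form contribution of the decaying drive to v over one step
    if abs(b - a) > 1e-12:
        drive = (a / (b - a)) * (decay_v - decay_g)
    else:
        drive = a * dt * decay_v
    spikes = [[] for _ in range(n)]
    pending: dict[int, list] = {}

    forced_steps: dict[int, list] = {}
    for nid, times in forced_times.items():
        for t in times:
            k = int(t / dt + 1e-6)
            if 0 <= k < n_steps:
                forced_steps.setdefault(k, []).append(idx[nid])

    for k in range(n_steps):
        t = k * dt
        for i, wmv in pending.pop(k, ()):
            g[i] += wmv

        # slack mirrors the engine's: ISI of exactly T_refractory is legal
        fired = []
        for i in sorted(set(forced_steps.get(k, ()))):
            if t >= refr_until[i] - 1e-9:
                fired.append(i)
        for i in range(n):
            if v[i] >= params.v_threshold and t >= refr_until[i] - 1e-9 \
                    and i not in fired:
                fired.append(i)
        for i in fired:
            spikes[i].append(t)
            v[i] = params.v_reset
            g[i] = 0.0
            refr_until[i] = t + params.t_refractory
            for j, wmv in out_edges[i]:
                pending.setdefault(k + d_steps, []).append((j, wmv))

        for i in range(n):
            if t >= refr_until[i] - 1e-9:
                v[i] = params.v_resting + (v[i] - params.v_resting) * decay_v \
                    + g[i] * drive
            g[i] *= decay_g

    return {ids[i]: spikes[i] for i in range(n)}


def random_network(rng, n_neurons=8, n_edges=20, w_lo=5.0, w_hi=11.0,
                   inhibitory_fraction=0.25):
    """Random small network with decisive (few-mV) weights.

    Returns (triplets, neuron_ids, stim_ids). Weights are kept large so
    that threshold crossings are steep and integrator comparisons are not
    dominated by grazing crossings.
    """
    ids = [f"r{i}" for i in range(n_neurons)]
    signs = np.where(rng.random(n_neurons) < inhibitory_fraction, -1.0, 1.0)
    pairs = [(i, j) for i in range(n_neurons) for j in range(n_neurons)
             if i != j]
    chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)),
                        replace=False)
    triplets = []
    for c in chosen:
        i, j = pairs[c]
        w = float(rng.uniform(w_lo, w_hi)) * signs[i]
        triplets.append((ids[i], ids[j], w))
    n_stim = int(rng.integers(1, 3))
    stim = list(rng.choice(ids, size=n_stim, replace=False))
    return triplets, ids, stim
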
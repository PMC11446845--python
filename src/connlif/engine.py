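"""Clock-driven leaky integrate-and-fire network integrator.

The model per neuron i::

    dv_i/dt = (g_i - (v_i - V_resting)) / T_mbr
    dg_i/dt = -g_i / tau
    g_i <- g_i + w[j, i]   upon a spike of presynaptic neuron j,
                           delivered T_dly after the spike

A neuron spikes when ``v >= V_threshold`` (closed boundary); on its own
spike ``v <- V_reset`` and ``g <- 0``, and for ``T_refractory`` the membrane
is clamped at V_reset with threshold checks suspended while g keeps
decaying and accumulating delayed increments. Both ODEs are linear, so the
integrator advances each fixed step with the exact propagator of the
coupled system (exponential update for g, and for v the closed-form
response to an exponentially decaying drive), which removes step-size
sensitivity; delayed increments and stimulus events are quantized to the
step grid.

Stimulation is Poisson: by default a stimulated neuron is *forced* to spike
at its Poisson-drawn times (times falling in the refractory dead period are
dropped), so the commanded rate r realizes approximately ``r/(1 + r*T_ref)``.
The alternative ``stim_mode="synapse"`` injects a suprathreshold drive
increment at the Poisson times instead of forcing the spike.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .params import LIFParameters
from .weights import SignedWeights

__all__ = ["StimulusEntry", "StimulusProtocol", "SpikeRecord",
           "poisson_spike_times", "simulate", "firing_rates",
           "psp_peak_factor"]


def _id_key(neuron_id) -> int:
    """Stable 32-bit key for a neuron id, for per-neuron seed derivation."""
    return zlib.crc32(str(neuron_id).encode())


def poisson_spike_times(rate_hz: float, start_ms: float, stop_ms: float,
                        seed=None, rng=None) -> np.ndarray:
    """Draw homogeneous Poisson process event times in [start, stop) ms.

    Deterministic given ``seed`` (or an explicit ``rng``). ``rate_hz <= 0``
    yields an empty array without consuming random numbers, so appending a
    zero-rate stimulus entry leaves all other draws untouched.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if rate_hz == 0 or stop_ms <= start_ms:
        return np.empty(0)
    if rng is None:
        rng = np.random.default_rng(seed)
    mean_gap_ms = 1000.0 / rate_hz
    # draw in blocks of expected size + slack until past the window
    expected = (stop_ms - start_ms) / mean_gap_ms
    times = []
    t = start_ms
    while t < stop_ms:
        gaps = rng.exponential(mean_gap_ms, size=max(16, int(expected)))
        cum = t + np.cumsum(gaps)
        times.append(cum)
        t = cum[-1]
    out = np.concatenate(times)
    return out[out < stop_ms]


@dataclass(frozen=True)
class StimulusEntry:
    """One stimulated neuron set: Poisson drive at ``rate_hz`` in a window."""
    neurons: tuple
    rate_hz: float
    start_ms: float = 0.0
    stop_ms: float | None = None  # None = protocol duration

    def __post_init__(self):
        object.__setattr__(self, "neurons", tuple(self.neurons))
        if self.rate_hz < 0:
            raise ValueError("stimulus rate must be non-negative")


@dataclass
class StimulusProtocol:
    """Full stimulation specification for a batch of trials.

    ``forced_spikes`` maps neuron id -> explicit spike times (ms), applied
    identically in every trial (used for oracle comparisons and analytic
    checks). ``injections`` are (neuron_id, time_ms, amount_mv) direct
    drive jumps added to g.
    """
    entries: list = field(default_factory=list)
    n_trials: int = 30
    duration_ms: float = 1000.0
    seed: int = 0
    forced_spikes: dict = field(default_factory=dict)
    injections: tuple = ()

    def __post_init__(self):
        self.entries = [e if isinstance(e, StimulusEntry) else StimulusEntry(**e)
                        for e in self.entries]
        for e in self.entries:
            stop = self.duration_ms if e.stop_ms is None else e.stop_ms
            if stop > self.duration_ms:
                raise ValueError("stimulus stop exceeds trial duration")


@dataclass
class SpikeRecord:
    """Per-trial spike times for every neuron, with run provenance."""
    trials: list                 # list over trials of {neuron_id: times array}
    neuron_ids: tuple
    duration_ms: float
    dt: float
    seed: int
    meta: dict = field(default_factory=dict)
    v_traces: list = field(default_factory=list)  # per trial: {id: v array}

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def spike_counts(self) -> pd.DataFrame:
        """Trials x neurons spike-count matrix."""
        data = [[len(tr.get(nid, ())) for nid in self.neuron_ids]
                for tr in self.trials]
        return pd.DataFrame(data, columns=list(self.neuron_ids))


def psp_peak_factor(params: LIFParameters) -> float:
    """Peak membrane depolarization per mV of drive increment.

    Closed form for the double-exponential response of v to a unit jump in
    g: with a = 1/T_mbr and b = 1/tau the peak, at t* = ln(b/a)/(b-a), is
    (a/(b-a))(e^{-a t*} - e^{-b t*}). Degenerate cases: tau = inf gives 1
    (full relaxation to V_rest + g), tau = T_mbr gives 1/e.
    """
    a = 1.0 / params.t_mbr
    b = 0.0 if math.isinf(params.tau) else 1.0 / params.tau
    if b == 0.0:
        return 1.0
    if abs(b - a) < 1e-12:
        return math.exp(-1.0)
    tstar = math.log(b / a) / (b - a)
    return (a / (b - a)) * (math.exp(-a * tstar) - math.exp(-b * tstar))


def _stimulus_times(protocol: StimulusProtocol, trial: int) -> dict:
    """Poisson times per stimulated neuron for one trial.

    Each (trial, entry, neuron) gets an independent generator seeded by
    ``(seed, trial, entry index, crc32(id))``, so adding unrelated neurons
    or zero-rate entries never perturbs existing draws.
    """
    out: dict = {}
    for e_idx, entry in enumerate(protocol.entries):
        if entry.rate_hz == 0:
            continue
        stop = protocol.duration_ms if entry.stop_ms is None else entry.stop_ms
        for nid in entry.neurons:
            rng = np.random.default_rng(
                (protocol.seed, trial, e_idx, _id_key(nid)))
            t = poisson_spike_times(entry.rate_hz, entry.start_ms, stop,
                                    rng=rng)
            if nid in out:
                t = np.sort(np.concatenate([out[nid], t]))
            out[nid] = t
    for nid, times in protocol.forced_spikes.items():
        t = np.asarray(times, dtype=float)
        if nid in out:
            t = np.sort(np.concatenate([out[nid], t]))
        out[nid] = t
    return out


def _simulate_trial(w: SignedWeights, p: LIFParameters, n_steps: int,
                    dt: float, stim_steps: dict, inj_steps: dict,
                    stim_mode: str, stim_weight: float,
                    record_idx=None) -> tuple:
    n = w.n_neurons
    mat = w.matrix
    v = np.full(n, p.v_resting)
    g = np.zeros(n)
    refr_until = np.full(n, -np.inf)

    a = 1.0 / p.t_mbr
    b = 0.0 if math.isinf(p.tau) else 1.0 / p.tau
    ea = math.exp(-a * dt)
    eb = math.exp(-b * dt)
    # exact response of v to an exponentially decaying g over one step
    if abs(b - a) > 1e-12:
        cg = (a / (b - a)) * (ea - eb)
    else:  # confluent case tau == t_mbr
        cg = a * dt * ea

    d_steps = int(round(p.t_dly / dt))
    m = d_steps + 1
    pending = np.zeros((m, n))
    spikes: list[list[float]] = [[] for _ in range(n)]
    trace = np.empty((n_steps, len(record_idx))) if record_idx is not None \
        else None

    for k in range(n_steps):
        t = k * dt
        slot = k % m
        if pending[slot].any():
            g += pending[slot]
            pending[slot] = 0.0
        if k in inj_steps:
            idx, amt = inj_steps[k]
            np.add.at(g, idx, amt)

        # tiny slack so ISIs of exactly T_refractory survive float rounding
        eligible = refr_until <= t + 1e-9
        fire = (v >= p.v_threshold) & eligible
        if k in stim_steps:
            sidx = stim_steps[k]
            if stim_mode == "force":
                fire[sidx] |= eligible[sidx]
            else:  # synapse mode: suprathreshold drive instead of forcing
                np.add.at(g, sidx, stim_weight)
                fire = (v >= p.v_threshold) & eligible

        if fire.any():
            fi = np.flatnonzero(fire)
            for i in fi:
                spikes[i].append(t)
            v[fi] = p.v_reset
            g[fi] = 0.0
            refr_until[fi] = t + p.t_refractory
            out = np.asarray(mat[fi].sum(axis=0)).ravel()
            pending[(k + d_steps) % m] += out

        if trace is not None:
            trace[k] = v[record_idx]
        active = refr_until <= t + 1e-9
        v = np.where(active, p.v_resting + (v - p.v_resting) * ea + g * cg, v)
        g *= eb
        if not np.isfinite(v).all():
            bad = w.neuron_ids[int(np.flatnonzero(~np.isfinite(v))[0])]
            raise SimulationError(
                f"non-finite membrane potential for neuron {bad} at t={t} ms")

    out = {w.neuron_ids[i]: np.asarray(s) for i, s in enumerate(spikes) if s}
    return out, trace


def simulate(w: SignedWeights, params: LIFParameters,
             protocol: StimulusProtocol, dt: float = 0.1,
             stim_mode: str = "force",
             stim_weight: float | None = None,
             record_v=None) -> SpikeRecord:
    """Integrate the network under the protocol and record all spikes.

    Each (trial, entry, neuron) stimulus stream has its own seeded
    generator derived from ``protocol.seed``; the run is fully
    deterministic given (weights, params, protocol, dt). ``record_v``
    optionally names neurons whose membrane-potential traces (sampled at
    the step grid) are kept in ``SpikeRecord.v_traces``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if dt > params.t_dly or dt > params.t_refractory:
        raise ConfigurationError(
            "dt must not exceed the transmission delay or the refractory "
            "period (event ordering would break)")
    if stim_mode not in ("force", "synapse"):
        raise ConfigurationError(f"unknown stim_mode {stim_mode!r}")
    if stim_weight is None:
        # drive increment whose PSP peak is 1.5x the rest-to-threshold gap
        gap = params.v_threshold - params.v_resting
        stim_weight = 1.5 * gap / psp_peak_factor(params)

    n_steps = int(round(protocol.duration_ms / dt))
    unknown = [nid for e in protocol.entries for nid in e.neurons
               if nid not in w.index]
    unknown += [nid for nid in protocol.forced_spikes if nid not in w.index]
    if unknown:
        raise ValueError(f"stimulated neuron(s) not in network: {unknown[:10]}")

    inj_map: dict[int, tuple[list, list]] = {}
    for nid, t_ms, amount in protocol.injections:
        k = int(t_ms / dt + 1e-6)
        inj_map.setdefault(k, ([], []))
        inj_map[k][0].append(w.index[nid])
        inj_map[k][1].append(float(amount))
    inj_steps = {k: (np.asarray(i), np.asarray(a))
                 for k, (i, a) in inj_map.items()}

    record_idx = None
    if record_v:
        record_idx = np.asarray([w.index[nid] for nid in record_v])

    trials, v_traces = [], []
    for trial in range(protocol.n_trials):
        times = _stimulus_times(protocol, trial)
        stim_map: dict[int, list] = {}
        for nid, ts in times.items():
            idx = w.index[nid]
            for k in np.unique((ts / dt + 1e-6).astype(int)):
                if 0 <= k < n_steps:
                    stim_map.setdefault(int(k), []).append(idx)
        stim_steps = {k: np.asarray(v) for k, v in stim_map.items()}
        spikes, trace = _simulate_trial(w, params, n_steps, dt, stim_steps,
                                        inj_steps, stim_mode, stim_weight,
                                        record_idx)
        trials.append(spikes)
        if trace is not None:
            v_traces.append({nid: trace[:, i]
                             for i, nid in enumerate(record_v)})
    meta = {"params": params.as_dict(), "stim_mode": stim_mode,
            "weights_meta": dict(w.meta)}
    return SpikeRecord(trials, w.neuron_ids, protocol.duration_ms, dt,
                       protocol.seed, meta, v_traces)


def firing_rates(records, duration_ms: float | None = None) -> pd.DataFrame:
    """Trial-averaged firing rates (Hz) per neuron.

    Accepts one SpikeRecord or a list sharing duration and neuron universe.
    Returns a DataFrame indexed by neuron id with ``rate_hz`` (mean over
    trials), ``sd_hz`` (across trials, ddof=1) and ``n_trials``; the
    per-trial rate matrix is attached as ``df.attrs["per_trial"]``. Neurons
    that never spiked are included at 0 Hz.
    """
    if isinstance(records, SpikeRecord):
        records = [records]
    if not records:
        raise ValueError("no spike records given")
    ids = records[0].neuron_ids
    dur = duration_ms if duration_ms is not None else records[0].duration_ms
    for r in records:
        if r.neuron_ids != ids:
            raise ValueError("records disagree on the neuron universe")
        if duration_ms is None and r.duration_ms != dur:
            raise ValueError("records disagree on trial duration")
    counts = pd.concat([r.spike_counts() for r in records], ignore_index=True)
    per_trial = counts * (1000.0 / dur)
    out = pd.DataFrame({
        "rate_hz": per_trial.mean(axis=0),
        "sd_hz": per_trial.std(axis=0, ddof=1) if len(per_trial) > 1
        else np.zeros(len(ids)),
        "n_trials": len(per_trial),
    })
    out.index.name = "neuron_id"
    out.attrs["per_trial"] = per_trial
    return out
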
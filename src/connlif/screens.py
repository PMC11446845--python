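"""In-silico experiment designs over a weighted connectome.

The screens mirror how connectome-model studies interrogate a circuit:

* activation screen — drive a sensory set across a rate grid, record every
  neuron's trial-averaged rate; responders are neurons with rate > 0 Hz;
* sufficiency screen — activate each top responder (or annotated cell-type
  unit) alone and measure readout firing;
* silencing screen — drive the sensory set while silencing one candidate at
  a time; a candidate has a silencing phenotype if the readout drops to
  <= 80% of control at any tested stimulation frequency;
* co-activation matrix — readout rate over a 2-D grid of two modalities;
* input-rate calibration — smallest grid rate reaching (or suppressing to)
  a target readout rate;
* shuffle control — repeat the experiment on weight-shuffled networks to
  show predictions depend on the true connectivity;
* robustness sweep — rerun a set of binary predictions under the
  w_syn +/-30%, inhibitory-ratio +/-50% and glutamate-excitatory variants.

All results are reproducible from (config, seeds): per-neuron stimulus
streams are keyed by (seed, trial, entry index, neuron id), so the zero-rate
marginals of a co-activation matrix are bit-identical to the single-modality
screen, and silencing an output-less neuron leaves spike trains bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .io import DEFAULT_INHIBITORY, aggregate_edges, assign_neuron_signs
from .params import LIFParameters
from .weights import SignedWeights, build_weight_matrix, silence_neurons, \
    shuffle_weights
from .engine import StimulusEntry, StimulusProtocol, firing_rates, simulate

DEFAULT_SILENCING_RATES = tuple(range(50, 121, 10))  # Hz, 50..120 step 10


@dataclass
class ScreenResult:
    """Long-format result of one screen plus its provenance."""
    kind: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def matrix(self, index: str, columns: str,
               values: str = "rate_hz") -> pd.DataFrame:
        """Wide (heatmap-ready) pivot of the long-format data."""
        return self.data.pivot(index=index, columns=columns, values=values)


def _sim_kwargs(kw: dict) -> dict:
    return {k: kw[k] for k in ("dt", "stim_mode") if k in kw}


def _rates(w: SignedWeights, params: LIFParameters, entries,
           n_trials: int, duration_ms: float, seed: int,
           **kw) -> pd.DataFrame:
    protocol = StimulusProtocol(entries=list(entries), n_trials=n_trials,
                                duration_ms=duration_ms, seed=seed)
    rec = simulate(w, params, protocol, **_sim_kwargs(kw))
    return firing_rates(rec)


def activation_screen(w: SignedWeights, params: LIFParameters, stim_set,
                      rate_grid, n_trials: int = 30,
                      duration_ms: float = 1000.0, seed: int = 0,
                      **kw) -> ScreenResult:
    """Drive ``stim_set`` at every grid rate; record all neurons' rates."""
    stim_set = tuple(stim_set)
    if not stim_set:
        raise ValueError("stim_set must be nonempty")
    if not len(list(rate_grid)):
        raise ValueError("rate_grid must be nonempty")
    rows = []
    for rate in rate_grid:
        rt = _rates(w, params, [StimulusEntry(stim_set, float(rate))],
                    n_trials, duration_ms, seed, **kw)
        row = rt.assign(stim_rate_hz=float(rate)).reset_index()
        row.attrs = {}
        rows.append(row)
    data = pd.concat(rows, ignore_index=True)
    meta = {"stim_set": stim_set, "rate_grid": [float(r) for r in rate_grid],
            "n_trials": n_trials, "duration_ms": duration_ms, "seed": seed}
    return ScreenResult("activation", data, meta)


def responder_set(result: ScreenResult, at_rate: float,
                  exclude_stimulated: bool = False) -> set:
    """Neurons with mean rate > 0 Hz at the given grid rate (strict)."""
    rates = result.meta.get("rate_grid", [])
    if float(at_rate) not in [float(r) for r in rates]:
        raise ValueError(f"rate {at_rate} not in screen grid {rates}")
    sub = result.data[result.data["stim_rate_hz"] == float(at_rate)]
    hits = set(sub.loc[sub["rate_hz"] > 0, "neuron_id"])
    if exclude_stimulated:
        hits -= set(result.meta.get("stim_set", ()))
    return hits


def top_responders(result: ScreenResult, n: int,
                   exclude=()) -> list:
    """Top-n responders ranked by rate at the maximum grid rate.

    Ties are broken by neuron id (string order) for reproducibility.
    """
    max_rate = max(result.meta["rate_grid"])
    sub = result.data[result.data["stim_rate_hz"] == max_rate].copy()
    sub = sub[~sub["neuron_id"].isin(set(exclude))]
    sub["_key"] = sub["neuron_id"].astype(str)
    sub = sub.sort_values(["rate_hz", "_key"], ascending=[False, True],
                          kind="stable")
    sub = sub[sub["rate_hz"] > 0]
    return list(sub["neuron_id"].head(n))


def sufficiency_screen(w: SignedWeights, params: LIFParameters, candidates,
                       rate_grid, readouts, units: dict | None = None,
                       n_trials: int = 30, duration_ms: float = 1000.0,
                       seed: int = 0, **kw) -> ScreenResult:
    """Activate each candidate alone across the grid; record readout rates.

    ``units`` maps a cell-type name to its member neuron ids; a candidate
    naming a unit activates all members together. A readout that is itself
    a candidate is allowed (flagged in meta).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    readouts = tuple(readouts)
    units = units or {}
    rows = []
    for cand in candidates:
        members = tuple(units.get(cand, (cand,)))
        for rate in rate_grid:
            rt = _rates(w, params, [StimulusEntry(members, float(rate))],
                        n_trials, duration_ms, seed, **kw)
            for ro in readouts:
                rows.append({"candidate": cand, "stim_rate_hz": float(rate),
                             "readout": ro,
                             "rate_hz": float(rt.loc[ro, "rate_hz"])})
    data = pd.DataFrame(rows)
    meta = {"rate_grid": [float(r) for r in rate_grid],
            "readouts": readouts, "n_trials": n_trials, "seed": seed,
            "readout_in_candidates": sorted(
                set(readouts) & set(candidates), key=str)}
    return ScreenResult("sufficiency", data, meta)


def silencing_screen(w: SignedWeights, params: LIFParameters, stim_set,
                     candidates, readout,
                     stim_rates=DEFAULT_SILENCING_RATES,
                     n_trials: int = 30, duration_ms: float = 1000.0,
                     seed: int = 0, units: dict | None = None,
                     **kw) -> ScreenResult:
    """One-at-a-time output silencing under sensory drive.

    The readout rate with a candidate silenced is normalized to the
    unsilenced control at the same stimulation frequency (identical
    stimulus seeds). Normalization is NaN where the control is 0. The
    readout itself is excluded from the candidate list.
    """
    stim_set = tuple(stim_set)
    units = units or {}
    candidates = [c for c in candidates if c != readout]
    controls = {}
    for rate in stim_rates:
        rt = _rates(w, params, [StimulusEntry(stim_set, float(rate))],
                    n_trials, duration_ms, seed, **kw)
        controls[float(rate)] = float(rt.loc[readout, "rate_hz"])
    if all(c == 0 for c in controls.values()):
        raise ValueError("control readout rate is 0 at every stimulation "
                         "frequency; nothing to normalize")
    rows = []
    for cand in candidates:
        members = tuple(units.get(cand, (cand,)))
        ws = silence_neurons(w, members)
        for rate in stim_rates:
            rt = _rates(ws, params, [StimulusEntry(stim_set, float(rate))],
                        n_trials, duration_ms, seed, **kw)
            r = float(rt.loc[readout, "rate_hz"])
            ctrl = controls[float(rate)]
            rows.append({"candidate": cand, "stim_rate_hz": float(rate),
                         "control_rate_hz": ctrl, "silenced_rate_hz": r,
                         "normalized": r / ctrl if ctrl > 0 else np.nan})
    data = pd.DataFrame(rows)
    meta = {"stim_set": stim_set, "readout": readout,
            "stim_rates": [float(r) for r in stim_rates],
            "controls": controls, "n_trials": n_trials, "seed": seed}
    return ScreenResult("silencing", data, meta)


def classify_silencing_phenotype(result: ScreenResult,
                                 threshold: float = 0.8) -> pd.Series:
    """Phenotype iff normalized readout <= threshold at >= 1 tested rate."""
    if result.data.empty:
        return pd.Series(dtype=bool)
    labels = (result.data.assign(hit=result.data["normalized"] <= threshold)
              .groupby("candidate", sort=False)["hit"].any())
    labels.name = "phenotype"
    return labels


def coactivation_matrix(w: SignedWeights, params: LIFParameters,
                        set_a, rates_a, set_b, rates_b, readout,
                        n_trials: int = 30, duration_ms: float = 1000.0,
                        seed: int = 0, **kw) -> ScreenResult:
    """Readout rate over the (rate_a, rate_b) grid of two disjoint sets."""
    set_a, set_b = tuple(set_a), tuple(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("stimulus sets must be disjoint")
    readouts = tuple(readout) if isinstance(readout, (list, tuple, set)) \
        else (readout,)
    rows = []
    for ra, rb in product(rates_a, rates_b):
        entries = [StimulusEntry(set_a, float(ra)),
                   StimulusEntry(set_b, float(rb))]
        rt = _rates(w, params, entries, n_trials, duration_ms, seed, **kw)
        for ro in readouts:
            rows.append({"rate_a_hz": float(ra), "rate_b_hz": float(rb),
                         "readout": ro,
                         "rate_hz": float(rt.loc[ro, "rate_hz"])})
    data = pd.DataFrame(rows)
    meta = {"set_a": set_a, "set_b": set_b,
            "rates_a": [float(r) for r in rates_a],
            "rates_b": [float(r) for r in rates_b],
            "n_trials": n_trials, "seed": seed}
    return ScreenResult("coactivation", data, meta)


def calibrate_input_rate(w: SignedWeights, params: LIFParameters, stim_set,
                         readout, target_rate: float, mode: str = "reach",
                         grid=None, opposing=None, n_trials: int = 30,
                         duration_ms: float = 1000.0, seed: int = 0,
                         **kw) -> float:
    """Grid-search the stimulation rate that reaches/suppresses a target.

    mode="reach": smallest grid rate whose readout rate >= target.
    mode="suppress": ``stim_set`` is the aversive set; ``opposing`` must be
    a (neuron set, rate_hz) pair giving the fixed appetitive drive, and the
    returned rate is the smallest aversive grid rate bringing the readout
    down to <= target. Raises :class:`CalibrationError` reporting the
    bracketing rates when the target is unreachable on the grid.
    """
    stim_set = tuple(stim_set)
    if grid is None:
        grid = np.arange(0.0, 201.0, 10.0)
    grid = [float(r) for r in grid]
    if mode not in ("reach", "suppress"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    base_entries = []
    if mode == "suppress":
        if opposing is None:
            raise ValueError("suppress mode requires the opposing "
                             "(neuron set, rate) drive")
        opp_set, opp_rate = opposing
        base_entries.append(StimulusEntry(tuple(opp_set), float(opp_rate)))

    achieved = []
    for rate in grid:
        entries = base_entries + [StimulusEntry(stim_set, rate)]
        rt = _rates(w, params, entries, n_trials, duration_ms, seed, **kw)
        r = float(rt.loc[readout, "rate_hz"])
        achieved.append(r)
        if (mode == "reach" and r >= target_rate) or \
           (mode == "suppress" and r <= target_rate):
            return rate
    lo, hi = min(achieved), max(achieved)
    raise CalibrationError(
        f"target {target_rate} Hz unreachable on grid {grid[0]}..{grid[-1]} "
        f"Hz (readout spanned [{lo:.3g}, {hi:.3g}] Hz)")


def overlap_analysis(named_sets: dict) -> pd.Series:
    """Venn-region cardinalities of >= 2 named sets.

    Returns a Series indexed by the tuple of member-set names of each
    non-empty region (elements belonging to exactly those sets). Counts
    satisfy inclusion-exclusion exactly by construction.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    names = list(named_sets)
    universe = set().union(*named_sets.values())
    counts: dict[tuple, int] = {}
    for el in universe:
        key = tuple(n for n in names if el in named_sets[n])
        counts[key] = counts.get(key, 0) + 1
    regions = [tuple(c) for r in range(1, len(names) + 1)
               for c in _combos(names, r)]
    return pd.Series([counts.get(k, 0) for k in regions],
                     index=pd.Index(regions, dtype=object, name="region",
                                    tupleize_cols=False),
                     name="count")


def _combos(names, r):
    from itertools import combinations
    return combinations(names, r)


def shuffle_control(w: SignedWeights, params: LIFParameters, stim_set,
                    stim_rate: float, readout, n_shuffles: int = 100,
                    base_seed: int = 0, n_trials: int = 30,
                    duration_ms: float = 1000.0, method: str = "permute",
                    **kw) -> ScreenResult:
    """Repeat the activation experiment on weight-shuffled networks.

    Row ``shuffle == -1`` is the unshuffled control. ``meta`` records
    ``fraction_active`` — the fraction of shuffles whose readout fired at
    all (> 0 Hz).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    stim_set = tuple(stim_set)
    entries = [StimulusEntry(stim_set, float(stim_rate))]
    rows = []
    rt = _rates(w, params, entries, n_trials, duration_ms, base_seed, **kw)
    rows.append({"shuffle": -1, "shuffle_seed": -1,
                 "rate_hz": float(rt.loc[readout, "rate_hz"])})
    for i in range(n_shuffles):
        seed_i = base_seed + 1 + i
        wsh = shuffle_weights(w, seed=seed_i, method=method)
        rt = _rates(wsh, params, entries, n_trials, duration_ms, base_seed,
                    **kw)
        rows.append({"shuffle": i, "shuffle_seed": seed_i,
                     "rate_hz": float(rt.loc[readout, "rate_hz"])})
    data = pd.DataFrame(rows)
    data["active"] = data["rate_hz"] > 0
    shuffled = data[data["shuffle"] >= 0]
    meta = {"stim_set": stim_set, "stim_rate_hz": float(stim_rate),
            "readout": readout, "n_shuffles": n_shuffles,
            "base_seed": base_seed, "method": method,
            "fraction_active": float(shuffled["active"].mean()),
            "control_rate_hz": float(data.loc[0, "rate_hz"])}
    return ScreenResult("shuffle_control", data, meta)


DEFAULT_VARIANTS = ("default", "wsyn_minus30", "wsyn_plus30",
                    "inh_ratio_minus50", "inh_ratio_plus50",
                    "glutamate_excitatory")


def robustness_sweep(sites: pd.DataFrame, params: LIFParameters, predict_fn,
                     cleft_cutoff: float = 50.0,
                     variants=DEFAULT_VARIANTS) -> pd.DataFrame:
    """Rerun a set of binary predictions under model-assumption variants.

    ``predict_fn(w, params) -> dict[str, bool]`` declares the predictions.
    Variants rebuild the weight matrix with w_syn scaled by 0.7/1.3, the
    inhibitory weights scaled by 0.5/1.5, or glutamate treated as
    excitatory (sign reassignment from the site table). Returns one row per
    variant with the prediction columns plus ``agreement`` — the fraction
    of predictions matching the default model.
    """
    edges = aggregate_edges(sites, cleft_cutoff)
    signs = assign_neuron_signs(sites, cleft_cutoff)

    def build(variant):
        p, inh_scale, sg = params, 1.0, signs
        if variant == "wsyn_minus30":
            p = params.replace(w_syn=params.w_syn * 0.7)
        elif variant == "wsyn_plus30":
            p = params.replace(w_syn=params.w_syn * 1.3)
        elif variant == "inh_ratio_minus50":
            inh_scale = 0.5
        elif variant == "inh_ratio_plus50":
            inh_scale = 1.5
        elif variant == "glutamate_excitatory":
            sg = assign_neuron_signs(sites, cleft_cutoff,
                                     inhibitory_set={"gaba"})
        elif variant != "default":
            raise ValueError(f"unknown variant {variant!r}")
        return build_weight_matrix(edges, sg, p, inh_scale=inh_scale), p

    rows = {}
    for variant in variants:
        wv, pv = build(variant)
        rows[variant] = predict_fn(wv, pv)
    table = pd.DataFrame.from_dict(rows, orient="index")
    ref = table.loc["default"] if "default" in table.index else table.iloc[0]
    table["agreement"] = (table == ref).mean(axis=1)
    table.index.name = "variant"
    return table
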
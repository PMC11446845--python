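"""Synthetic connectomes with planted ground truth.

Generators produce mutually consistent edge tables, site tables and
annotations so that every engine and screen behaviour can be exercised on
circuits whose correct outcome is known by construction: an all-excitatory
feedforward chain, a bilateral crossed motif with a contralateral bias, a
disinhibition gate, and random background connectomes with a heavy-tailed
(discretized lognormal) synapse-count distribution and a stated inhibitory
fraction. Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NT_TYPES

#: Transmitter composition of the fly central brain used as the default for
#: random connectomes: ~55% ACh, 24% Glu, 14% GABA, remainder monoamines.
DEFAULT_NT_FRACTIONS = {"ach": 0.55, "glut": 0.24, "gaba": 0.14,
                        "da": 0.03, "oct": 0.02, "ser": 0.02}
INHIBITORY_NTS = ("gaba", "glut")


@dataclass
class SynthCircuit:
    """A generated connectome: edges, per-site predictions, annotations.

    ``annotations`` has one row per neuron: neuron_id, cell_type, side,
    role (sensory / inter / motor / background), transmitter and the
    planted sign.
    """
    edges: pd.DataFrame
    sites: pd.DataFrame | None
    annotations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def neurons(self, role=None, cell_type=None, side=None) -> list:
        """Neuron ids filtered by annotation tags."""
        df = self.annotations
        for col, val in (("role", role), ("cell_type", cell_type),
                         ("side", side)):
            if val is not None:
                df = df[df[col] == val]
        return list(df["neuron_id"])


def _sites_for_edges(edges: pd.DataFrame, transmitter_of: dict,
                     rng: np.random.Generator) -> pd.DataFrame:
    """One site row per synapse, unanimous for the pre neuron's transmitter.

    Cleft scores are drawn in [60, 160), comfortably above the default
    cutoff of 50, so aggregation reproduces the edge table exactly.
    """
    rows = {c: [] for c in ("pre_id", "post_id", "cleft_score")}
    nt_cols = {t: [] for t in NT_TYPES}
    for pre, post, count in edges.itertuples(index=False):
        nt = transmitter_of[pre]
        for _ in range(int(count)):
            rows["pre_id"].append(pre)
            rows["post_id"].append(post)
            rows["cleft_score"].append(float(rng.integers(60, 160)))
            for t in NT_TYPES:
                if t == nt:
                    nt_cols[t].append(float(rng.uniform(0.6, 0.95)))
                else:
                    nt_cols[t].append(float(rng.uniform(0.0, 0.3)))
    return pd.DataFrame({**rows, **nt_cols})


def _annotations(ids, cell_types, sides, roles, transmitters) -> pd.DataFrame:
    sign = [-1 if t in INHIBITORY_NTS else 1 for t in transmitters]
    return pd.DataFrame({"neuron_id": ids, "cell_type": cell_types,
                         "side": sides, "role": roles,
                         "transmitter": transmitters, "sign": sign})


def make_feedforward_chain(layers=(5, 3, 1), fan: int | None = None,
                           syn_count: int = 30, seed: int = 0) -> SynthCircuit:
    """All-excitatory layered chain from sensory to motor neurons.

    Each neuron of layer l projects to ``fan`` neurons of layer l+1
    (round-robin, guaranteeing every downstream neuron at least one input),
    or to all of them when ``fan`` is None. All sites are unanimous ACh.
    """
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    rng = np.random.default_rng(seed)
    ids_by_layer = [[f"l{li}n{j}" for j in range(sz)]
                    for li, sz in enumerate(layers)]
    edge_rows = []
    for li in range(len(layers) - 1):
        pre_ids, post_ids = ids_by_layer[li], ids_by_layer[li + 1]
        k = len(post_ids) if fan is None else min(fan, len(post_ids))
        for j, pre in enumerate(pre_ids):
            for off in range(k):
                post = post_ids[(j + off) % len(post_ids)]
                edge_rows.append((pre, post, syn_count))
    edges = pd.DataFrame(edge_rows,
                         columns=["pre_id", "post_id", "syn_count"])
    all_ids = [nid for layer in ids_by_layer for nid in layer]
    roles = (["sensory"] * layers[0]
             + ["inter"] * sum(layers[1:-1])
             + ["motor"] * layers[-1])
    cell_types = [f"layer{li}" for li, sz in enumerate(layers)
                  for _ in range(sz)]
    ann = _annotations(all_ids, cell_types, ["left"] * len(all_ids), roles,
                       ["ach"] * len(all_ids))
    sites = _sites_for_edges(edges, dict(zip(all_ids, ann["transmitter"])),
                             rng)
    return SynthCircuit(edges, sites, ann,
                        {"kind": "feedforward_chain", "layers": list(layers),
                         "fan": fan, "syn_count": syn_count, "seed": seed})


def make_crossed_circuit(seed: int = 0, n_sensory: int = 4,
                         contra_syn: int = 40, ipsi_syn: int = 10,
                         symmetric: bool = False) -> SynthCircuit:
    """Bilateral motif with a planted contralateral bias.

    Sensory neurons of each side project more strongly to the motor readout
    of the *opposite* side (``contra_syn`` vs ``ipsi_syn`` synapses);
    ``symmetric=True`` levels both at their mean.
    """
    rng = np.random.default_rng(seed)
    if symmetric:
        contra_syn = ipsi_syn = (contra_syn + ipsi_syn) // 2
    sides = ("left", "right")
    other = {"left": "right", "right": "left"}
    ids, cts, sds, roles, nts = [], [], [], [], []
    edge_rows = []
    for side in sides:
        motor = f"{side}_mn"
        ids.append(motor); cts.append("mn"); sds.append(side)
        roles.append("motor"); nts.append("ach")
    for side in sides:
        for i in range(n_sensory):
            nid = f"{side}_grn{i}"
            ids.append(nid); cts.append("grn"); sds.append(side)
            roles.append("sensory"); nts.append("ach")
            edge_rows.append((nid, f"{other[side]}_mn", contra_syn))
            edge_rows.append((nid, f"{side}_mn", ipsi_syn))
    edges = pd.DataFrame(edge_rows,
                         columns=["pre_id", "post_id", "syn_count"])
    ann = _annotations(ids, cts, sds, roles, nts)
    sites = _sites_for_edges(edges, dict(zip(ids, nts)), rng)
    return SynthCircuit(edges, sites, ann,
                        {"kind": "crossed_circuit", "seed": seed,
                         "contra_syn": contra_syn, "ipsi_syn": ipsi_syn,
                         "symmetric": symmetric})


def make_inhibitory_gate(seed: int = 0, syn_count: int = 150) -> SynthCircuit:
    """Disinhibition chain: inhibitory A -> inhibitory B -> excitatory C -> readout.

    Exhibits the model's zero-basal-rate consequence: driving A alone
    leaves the readout silent (inhibition onto an inactive neuron has no
    effect); driving C alone fires the readout; driving A while B and C
    receive tonic drive raises the readout above the no-A condition.
    """
    rng = np.random.default_rng(seed)
    ids = ["gate_a", "gate_b", "driver_c", "readout"]
    nts = ["gaba", "gaba", "ach", "ach"]
    edge_rows = [("gate_a", "gate_b", syn_count),
                 ("gate_b", "driver_c", syn_count),
                 ("driver_c", "readout", syn_count)]
    edges = pd.DataFrame(edge_rows,
                         columns=["pre_id", "post_id", "syn_count"])
    ann = _annotations(ids, ["gate", "gate", "driver", "mn"],
                       ["left"] * 4, ["inter", "inter", "inter", "motor"],
                       nts)
    sites = _sites_for_edges(edges, dict(zip(ids, nts)), rng)
    return SynthCircuit(edges, sites, ann,
                        {"kind": "inhibitory_gate", "seed": seed,
                         "syn_count": syn_count})


def make_random_connectome(n: int = 500, density: float = 0.01,
                           count_distribution=("lognormal",
                                               {"mean": 0.7, "sigma": 1.0}),
                           inhibitory_fraction: float = 0.38,
                           seed: int = 0,
                           include_sites: bool = True) -> SynthCircuit:
    """Directed random background connectome.

    Edges are i.i.d. Bernoulli(density) over ordered pairs (no self
    loops); synapse counts are a discretized lognormal (heavy tail, as in
    real connectomes). Each neuron's transmitter is drawn so that the
    expected inhibitory fraction (GABA + Glu) matches
    ``inhibitory_fraction``, keeping the relative GABA:Glu and
    ACh:monoamine proportions of the fly brain.
    """
    if n < 2:
        raise ValueError("need at least two neurons")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"n{i:05d}" for i in range(n)]

    # transmitter draw honoring the requested inhibitory fraction
    base = DEFAULT_NT_FRACTIONS
    inh_base = sum(base[t] for t in INHIBITORY_NTS)
    probs = {}
    for t, f in base.items():
        if t in INHIBITORY_NTS:
            probs[t] = f / inh_base * inhibitory_fraction
        else:
            probs[t] = f / (1 - inh_base) * (1 - inhibitory_fraction)
    nt_names = list(probs)
    nts = rng.choice(nt_names, size=n, p=[probs[t] for t in nt_names])

    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    dist_name, dist_kw = count_distribution
    if dist_name != "lognormal":
        raise ValueError(f"unknown count distribution {dist_name!r}")
    raw = rng.lognormal(dist_kw.get("mean", 0.7), dist_kw.get("sigma", 1.0),
                        size=len(pre_idx))
    counts = np.maximum(1, np.rint(raw)).astype(np.int64)
    ids_arr = np.asarray(ids, dtype=object)
    edges = pd.DataFrame({"pre_id": ids_arr[pre_idx],
                          "post_id": ids_arr[post_idx],
                          "syn_count": counts})
    ann = _annotations(ids, ["background"] * n, ["left"] * n,
                       ["background"] * n, list(nts))
    sites = _sites_for_edges(edges, dict(zip(ids, nts)), rng) \
        if include_sites else None
    return SynthCircuit(edges, sites, ann,
                        {"kind": "random_connectome", "n": n,
                         "density": density, "seed": seed,
                         "inhibitory_fraction": inhibitory_fraction,
                         "count_distribution": [dist_name, dict(dist_kw)]})


def make_planted_pathway(n_background: int = 500, density: float = 0.005,
                         n_sensory: int = 5, seed: int = 0) -> SynthCircuit:
    """A strong sensory->relay->readout pathway inside random background.

    The planted pathway uses decisive synapse counts; the background is a
    random connectome whose neurons receive no stimulation (and so stay
    silent on their own), plus sparse cross edges between the pathway and
    the background so that weight shuffles can reassign strong weights
    anywhere. Used for shuffle-control experiments: the readout should
    fire with the true weights and fall silent in nearly every shuffle.
    Pathway roles are tagged in the annotations (sensory / relay / motor).
    """
    rng = np.random.default_rng(seed)
    path_ids = [f"grn{i}" for i in range(n_sensory)] + ["relay", "mn"]
    roles = ["sensory"] * n_sensory + ["relay", "motor"]
    edge_rows = [(f"grn{i}", "relay", 40) for i in range(n_sensory)]
    edge_rows.append(("relay", "mn", 220))
    path_edges = pd.DataFrame(edge_rows,
                              columns=["pre_id", "post_id", "syn_count"])
    path_ann = _annotations(path_ids, ["pathway"] * len(path_ids),
                            ["left"] * len(path_ids), roles,
                            ["ach"] * len(path_ids))
    path_sites = _sites_for_edges(path_edges,
                                  dict(zip(path_ids, ["ach"] * len(path_ids))),
                                  rng)
    pathway = SynthCircuit(path_edges, path_sites, path_ann)
    background = make_random_connectome(n=n_background, density=density,
                                        seed=seed + 1)
    bg_ids = background.neurons()
    cross_rows = []
    for i in range(n_sensory):  # pathway output into the background
        for tgt in rng.choice(bg_ids, size=3, replace=False):
            cross_rows.append((f"grn{i}", tgt, 2))
    for src in rng.choice(bg_ids, size=10, replace=False):
        cross_rows.append((src, "mn", 2))  # background inputs to readout
    cross = pd.DataFrame(cross_rows,
                         columns=["pre_id", "post_id", "syn_count"])
    merged = merge_circuits(pathway, background, extra_edges=cross)
    merged.meta.update({"kind": "planted_pathway", "seed": seed,
                        "n_background": n_background, "density": density})
    return merged


def merge_circuits(*circuits: SynthCircuit,
                   extra_edges: pd.DataFrame | None = None) -> SynthCircuit:
    """Concatenate circuits with disjoint neuron ids into one connectome.

    ``extra_edges`` may add cross-circuit edges (e.g. to embed a planted
    pathway in random background).
    """
    all_ids = [set(c.annotations["neuron_id"]) for c in circuits]
    for i in range(len(all_ids)):
        for j in range(i + 1, len(all_ids)):
            clash = all_ids[i] & all_ids[j]
            if clash:
                raise ValueError(f"neuron id collision: {sorted(clash)[:5]}")
    edges = pd.concat([c.edges for c in circuits], ignore_index=True)
    if extra_edges is not None:
        edges = pd.concat([edges, extra_edges], ignore_index=True)
    sites = None
    if all(c.sites is not None for c in circuits):
        sites = pd.concat([c.sites for c in circuits], ignore_index=True)
    ann = pd.concat([c.annotations for c in circuits], ignore_index=True)
    return SynthCircuit(edges, sites, ann,
                        {"kind": "merged",
                         "parts": [c.meta.get("kind") for c in circuits]})


def planted_signs(circuit: SynthCircuit) -> pd.DataFrame:
    """Sign table from the planted annotations (same shape as
    :func:`connlif.io.assign_neuron_signs` output)."""
    ann = circuit.annotations
    out = pd.DataFrame({
        "sign": ann["sign"].to_numpy(),
        "fraction_inhibitory_sites": np.where(ann["sign"] < 0, 1.0, 0.0),
        "dominant_transmitter": ann["transmitter"].to_numpy(),
        "n_sites": 0,
        "flagged": False,
    }, index=pd.Index(ann["neuron_id"], name="neuron_id"))
    return out
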
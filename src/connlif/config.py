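"""Config-driven experiment runner with replayable run manifests.

A run is described by a small YAML/dict config naming the experiment kind,
the input tables (or a synthetic-circuit spec), the stimulus sets, the
readout and the simulation settings. ``run_config`` dispatches to the
matching screen, writes a long-format CSV per result plus a
``manifest.json`` capturing the config snapshot, input-file hashes, seeds
and output hashes — enough to re-run the experiment bit-exactly with
``replay_manifest``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .io import aggregate_edges, assign_neuron_signs, read_edge_table, \
    read_site_table
from .params import LIFParameters
from .weights import build_weight_matrix
from . import cluster as _cluster
from . import screens as _screens
from . import synth as _synth

EXPERIMENTS = ("activation", "silencing", "coactivation", "calibration",
               "shuffle_control", "robustness", "cluster")

_SYNTH_KINDS = {
    "feedforward_chain": _synth.make_feedforward_chain,
    "crossed_circuit": _synth.make_crossed_circuit,
    "inhibitory_gate": _synth.make_inhibitory_gate,
    "random_connectome": _synth.make_random_connectome,
}


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict
    outputs: dict
    seeds: dict
    version: str
    elapsed_s: float
    params: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True, default=str))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(cfg: dict, key: str, context: str = "config"):
    if key not in cfg:
        raise SchemaError(f"{context} is missing required field {key!r}")
    return cfg[key]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _load_inputs(cfg: dict):
    """Return (edges, sites, annotations, input_hashes)."""
    hashes = {}
    if "synth" in cfg:
        spec = dict(cfg["synth"])
        kind = _require(spec, "kind", "synth spec")
        if kind not in _SYNTH_KINDS:
            raise SchemaError(f"unknown synthetic circuit kind {kind!r}")
        kwargs = {k: v for k, v in spec.items() if k != "kind"}
        if "layers" in kwargs:
            kwargs["layers"] = tuple(kwargs["layers"])
        circuit = _SYNTH_KINDS[kind](**kwargs)
        return circuit.edges, circuit.sites, circuit.annotations, hashes
    inputs = _require(cfg, "inputs")
    edges = sites = ann = None
    if "edges" in inputs:
        path = inputs["edges"]
        if not Path(path).exists():
            raise SchemaError(f"input file not found: {path}")
        edges = read_edge_table(path, dialect=inputs.get("dialect", "generic"))
        hashes["edges"] = _sha256(path)
    if "sites" in inputs:
        path = inputs["sites"]
        if not Path(path).exists():
            raise SchemaError(f"input file not found: {path}")
        sites = read_site_table(path, dialect=inputs.get("dialect", "generic"))
        hashes["sites"] = _sha256(path)
    if "annotations" in inputs:
        path = inputs["annotations"]
        ann = pd.read_csv(path)
        hashes["annotations"] = _sha256(path)
    if edges is None and sites is not None:
        edges = aggregate_edges(sites, cfg.get("cleft_cutoff", 50.0))
    if edges is None:
        raise SchemaError("inputs must provide 'edges' or 'sites'")
    return edges, sites, ann, hashes


def _resolve_set(spec, annotations) -> list:
    """A neuron set is either an explicit id list or an annotation query."""
    if isinstance(spec, (list, tuple)):
        return list(spec)
    if isinstance(spec, dict):
        if annotations is None:
            raise SchemaError("annotation query used but no annotations "
                              "table was provided")
        df = annotations
        for col, val in spec.items():
            if col not in df.columns:
                raise SchemaError(f"annotation query names unknown column "
                                  f"{col!r}")
            df = df[df[col] == val]
        return list(df["neuron_id"])
    raise SchemaError(f"cannot interpret neuron-set spec {spec!r}")


def _build_weights(cfg, edges, sites, params):
    cutoff = cfg.get("cleft_cutoff", 50.0)
    if sites is not None:
        signs = assign_neuron_signs(sites, cutoff)
    elif "signs" in cfg.get("inputs", {}):
        signs = pd.read_csv(cfg["inputs"]["signs"], index_col="neuron_id")
    else:
        # no transmitter information: treat every neuron as excitatory
        import numpy as np
        ids = sorted(set(edges["pre_id"]) | set(edges["post_id"]), key=str)
        signs = pd.DataFrame({"sign": np.ones(len(ids), dtype=int)},
                             index=pd.Index(ids, name="neuron_id"))
    return build_weight_matrix(edges, signs, params,
                               inh_scale=cfg.get("inh_scale", 1.0))


def run_config(config, output_dir=None) -> RunManifest:
    """Run the experiment named by the config; write outputs + manifest."""
    t0 = time.monotonic()
    cfg = load_config(config)
    kind = _require(cfg, "experiment")
    if kind not in EXPERIMENTS:
        raise SchemaError(f"unknown experiment kind {kind!r}; expected one "
                          f"of {EXPERIMENTS}")
    out_dir = Path(output_dir or cfg.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    params = LIFParameters(**cfg.get("lif_params", {}))
    sim = cfg.get("simulation", {})
    sim_kw = {"n_trials": int(sim.get("n_trials", 30)),
              "duration_ms": float(sim.get("duration_ms", 1000.0)),
              "seed": int(sim.get("seed", 0)),
              "dt": float(sim.get("dt", 0.1))}

    edges, sites, ann, hashes = _load_inputs(cfg)
    outputs: dict[str, str] = {}

    def write(df: pd.DataFrame, name: str, index=False):
        path = out_dir / name
        df.to_csv(path, index=index, float_format="%.10g")
        outputs[name] = _sha256(path)

    if kind == "cluster":
        sources = _resolve_set(_require(cfg, "sources"), ann)
        partners = _resolve_set(_require(cfg, "partners"), ann)
        profile = _cluster.connectivity_vectors(
            edges, sources, partners,
            direction=cfg.get("direction", "outgoing"))
        res = _cluster.cluster_modalities(
            profile, k=cfg.get("k"), height=cfg.get("height"),
            linkage_method=cfg.get("linkage", "average"),
            binarize=cfg.get("binarize", False))
        write(res.labels.rename_axis("neuron_id").reset_index(),
              "cluster_labels.csv")
        (out_dir / "dendrogram.nwk").write_text(_cluster.to_newick(res))
        outputs["dendrogram.nwk"] = _sha256(out_dir / "dendrogram.nwk")
    else:
        w = _build_weights(cfg, edges, sites, params)
        stim = None
        if kind != "robustness":
            stim_cfg = _require(cfg, "stimulus")
            stim = _resolve_set(_require(stim_cfg, "set", "stimulus"), ann)
        if kind == "activation":
            grid = _require(cfg["stimulus"], "rates", "stimulus")
            res = _screens.activation_screen(w, params, stim, grid, **sim_kw)
            write(res.data, "activation_rates.csv")
        elif kind == "silencing":
            grid = cfg["stimulus"].get("rates",
                                       list(_screens.DEFAULT_SILENCING_RATES))
            readout = _require(cfg, "readout")
            cands = _resolve_set(_require(cfg, "candidates"), ann)
            res = _screens.silencing_screen(w, params, stim, cands, readout,
                                            stim_rates=grid, **sim_kw)
            labels = _screens.classify_silencing_phenotype(
                res, cfg.get("phenotype_threshold", 0.8))
            write(res.data, "silencing_normalized.csv")
            write(labels.reset_index(), "silencing_phenotypes.csv")
        elif kind == "coactivation":
            b = _require(cfg, "stimulus_b")
            set_b = _resolve_set(b["set"], ann)
            res = _screens.coactivation_matrix(
                w, params, stim, _require(cfg["stimulus"], "rates"),
                set_b, _require(b, "rates", "stimulus_b"),
                _require(cfg, "readout"), **sim_kw)
            write(res.data, "coactivation_rates.csv")
        elif kind == "calibration":
            rate = _screens.calibrate_input_rate(
                w, params, stim, _require(cfg, "readout"),
                float(_require(cfg, "target_rate")),
                mode=cfg.get("mode", "reach"),
                grid=cfg["stimulus"].get("rates"), **sim_kw)
            write(pd.DataFrame([{"calibrated_rate_hz": rate}]),
                  "calibration.csv")
        elif kind == "shuffle_control":
            res = _screens.shuffle_control(
                w, params, stim,
                float(_require(cfg["stimulus"], "rate", "stimulus")),
                _require(cfg, "readout"),
                n_shuffles=int(cfg.get("n_shuffles", 100)),
                base_seed=sim_kw["seed"], n_trials=sim_kw["n_trials"],
                duration_ms=sim_kw["duration_ms"], dt=sim_kw["dt"],
                method=cfg.get("shuffle_method", "permute"))
            write(res.data, "shuffle_control.csv")
        elif kind == "robustness":
            if sites is None:
                raise SchemaError("robustness sweep needs a site table to "
                                  "recompute transmitter signs")
            preds = _require(cfg, "predictions")

            def predict_fn(wv, pv):
                out = {}
                for p in preds:
                    s = _resolve_set(p["set"], ann)
                    rt = _screens._rates(
                        wv, pv, [_screens.StimulusEntry(tuple(s),
                                                        float(p["rate"]))],
                        sim_kw["n_trials"], sim_kw["duration_ms"],
                        sim_kw["seed"], dt=sim_kw["dt"])
                    out[p["name"]] = bool(rt.loc[p["readout"],
                                                 "rate_hz"] > 0)
                return out

            table = _screens.robustness_sweep(
                sites, params, predict_fn,
                cleft_cutoff=cfg.get("cleft_cutoff", 50.0))
            write(table.reset_index(), "robustness.csv")

    manifest = RunManifest(config=cfg, input_hashes=hashes, outputs=outputs,
                           seeds={"seed": sim_kw["seed"]},
                           version=__version__,
                           elapsed_s=round(time.monotonic() - t0, 3),
                           params=params.as_dict())
    manifest.save(out_dir / "manifest.json")
    return manifest


def replay_manifest(manifest_path, output_dir=None) -> RunManifest:
    """Re-run the experiment captured in a manifest, bit-exactly."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_config(manifest["config"], output_dir=output_dir)
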
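"""Reading connectome tables and assigning per-neuron transmitter signs.

Two table kinds flow through the package:

* a *site table*: one row per presynaptic site, carrying a cleft confidence
  score and one prediction score per transmitter (GABA, acetylcholine,
  glutamate, dopamine, octopamine, serotonin);
* an *edge table*: one row per directed (pre, post) neuron pair with the
  aggregated synapse count.

Edge direction is always pre -> post, the direction of chemical
transmission. Tables are plain :class:`pandas.DataFrame` objects with
canonical column names; named input dialects map foreign column headers
(e.g. a Flywire-style export) onto the canonical schema.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

#: Canonical transmitter column order. This order is also the deterministic
#: tie-break priority when a site's per-transmitter scores are tied.
NT_TYPES = ("gaba", "ach", "glut", "da", "oct", "ser")

#: Transmitters treated as inhibitory by default (glutamate is inhibitory in
#: the fly central brain under the default assumption; monoamines excitatory).
DEFAULT_INHIBITORY = frozenset({"gaba", "glut"})

SITE_COLUMNS = ("pre_id", "post_id", "cleft_score") + NT_TYPES
EDGE_COLUMNS = ("pre_id", "post_id", "syn_count")

#: Input dialects: canonical column -> column name in the foreign file.
#: The "flywire" dialect matches the public synapse-table export headers.
SITE_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "flywire": {
        "pre_id": "pre_pt_root_id",
        "post_id": "post_pt_root_id",
    },
}
EDGE_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "flywire": {
        "pre_id": "pre_pt_root_id",
        "post_id": "post_pt_root_id",
        "syn_count": "syn_count",
    },
}


def _read_delimited(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def _apply_dialect(df: pd.DataFrame, mapping: dict[str, str],
                   required: tuple[str, ...]) -> pd.DataFrame:
    rename = {src: canon for canon, src in mapping.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_site_table(path, dialect: str = "generic", sep: str | None = None,
                    columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a presynaptic-site table from a delimited text file.

    Parameters
    ----------
    path : file path (CSV by default; ``.tsv`` implies tab separation).
    dialect : named column mapping ("generic" or "flywire").
    columns : optional explicit mapping canonical-name -> file column name,
        overriding the dialect.

    Rows with unparseable or negative numeric fields are dropped with a
    logged warning reporting their row indices; well-formed rows are kept.
    """
    if dialect not in SITE_DIALECTS:
        raise SchemaError(f"unknown site-table dialect {dialect!r}")
    mapping = dict(SITE_DIALECTS[dialect])
    if columns:
        mapping.update(columns)
    df = _apply_dialect(_read_delimited(path, sep), mapping, SITE_COLUMNS)
    df = df.loc[:, list(SITE_COLUMNS)].copy()

    numeric = ("cleft_score",) + NT_TYPES
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[list(numeric)].isna().any(axis=1) | (df["cleft_score"] < 0)
    if bad.any():
        idx = df.index[bad].tolist()
        logger.warning("read_site_table: rejected %d malformed row(s) at "
                       "index %s", len(idx), idx)
        df = df.loc[~bad]
    return df.reset_index(drop=True)


def read_edge_table(path, dialect: str = "generic", sep: str | None = None,
                    columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a directed edge table (pre_id, post_id, syn_count)."""
    if dialect not in EDGE_DIALECTS:
        raise SchemaError(f"unknown edge-table dialect {dialect!r}")
    mapping = dict(EDGE_DIALECTS[dialect])
    if columns:
        mapping.update(columns)
    df = _apply_dialect(_read_delimited(path, sep), mapping, EDGE_COLUMNS)
    df = df.loc[:, list(EDGE_COLUMNS)].copy()
    df["syn_count"] = pd.to_numeric(df["syn_count"], errors="coerce")
    bad = df["syn_count"].isna() | (df["syn_count"] < 1)
    if bad.any():
        idx = df.index[bad].tolist()
        logger.warning("read_edge_table: rejected %d malformed row(s) at "
                       "index %s", len(idx), idx)
        df = df.loc[~bad]
    df["syn_count"] = df["syn_count"].astype(np.int64)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as delimited text, round-tripping integers exactly."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def site_argmax_transmitter(sites: pd.DataFrame) -> pd.Series:
    """Arg-max transmitter per site; ties broken by `NT_TYPES` priority."""
    scores = sites[list(NT_TYPES)].to_numpy(dtype=float)
    # np.argmax returns the first maximum, which implements the documented
    # fixed priority order.
    return pd.Series(np.asarray(NT_TYPES)[np.argmax(scores, axis=1)],
                     index=sites.index, name="transmitter")


def assign_neuron_signs(sites: pd.DataFrame, cleft_cutoff: float = 50.0,
                        inhibitory_set=DEFAULT_INHIBITORY) -> pd.DataFrame:
    """Assign each presynaptic neuron a sign from its site-level predictions.

    Sites with ``cleft_score < cleft_cutoff`` are dropped. Each surviving
    site votes for its arg-max transmitter; a neuron is inhibitory (sign -1)
    iff *strictly more than half* of its surviving sites vote for a
    transmitter in ``inhibitory_set``, else excitatory (+1). Passing
    ``inhibitory_set={"gaba"}`` yields the glutamate-excitatory variant.

    Returns a DataFrame indexed by neuron id with columns ``sign``,
    ``fraction_inhibitory_sites``, ``dominant_transmitter``, ``n_sites``
    and ``flagged`` (True for neurons whose every site fell below the
    cutoff; these default to +1 with a logged warning so users can
    override — their outputs are typically absent anyway).
    """
    inhibitory_set = frozenset(inhibitory_set)
    unknown = inhibitory_set - set(NT_TYPES)
    if unknown:
        raise ValueError(f"unknown transmitter(s) in inhibitory_set: {unknown}")

    all_pre = pd.unique(sites["pre_id"])
    surviving = sites[sites["cleft_score"] >= cleft_cutoff]
    out = pd.DataFrame(index=pd.Index(all_pre, name="neuron_id"))
    out["sign"] = 1
    out["fraction_inhibitory_sites"] = 0.0
    out["dominant_transmitter"] = None
    out["n_sites"] = 0
    out["flagged"] = True

    if len(surviving):
        votes = surviving[["pre_id"]].copy()
        votes["transmitter"] = site_argmax_transmitter(surviving)
        votes["inhib"] = votes["transmitter"].isin(inhibitory_set)
        grp = votes.groupby("pre_id", sort=False)
        frac = grp["inhib"].mean()
        n = grp.size()
        # dominant transmitter = most common vote, priority order on ties
        counts = (votes.groupby(["pre_id", "transmitter"], sort=False)
                  .size().rename("k").reset_index())
        counts["prio"] = counts["transmitter"].map(
            {t: i for i, t in enumerate(NT_TYPES)})
        counts = counts.sort_values(["k", "prio"], ascending=[False, True],
                                    kind="stable")
        dominant = counts.drop_duplicates("pre_id").set_index("pre_id")[
            "transmitter"]
        ids = frac.index
        out.loc[ids, "fraction_inhibitory_sites"] = frac
        out.loc[ids, "sign"] = np.where(frac > 0.5, -1, 1)
        out.loc[ids, "dominant_transmitter"] = dominant
        out.loc[ids, "n_sites"] = n
        out.loc[ids, "flagged"] = False

    n_flagged = int(out["flagged"].sum())
    if n_flagged:
        logger.warning("assign_neuron_signs: %d neuron(s) had no site above "
                       "the cleft cutoff %.1f; defaulted to sign +1",
                       n_flagged, cleft_cutoff)
    out["sign"] = out["sign"].astype(np.int64)
    out["n_sites"] = out["n_sites"].astype(np.int64)
    return out


def aggregate_edges(sites: pd.DataFrame,
                    cleft_cutoff: float = 50.0) -> pd.DataFrame:
    """Aggregate surviving sites into a directed edge table.

    ``syn_count(pre, post)`` is the number of sites of that ordered pair
    with ``cleft_score >= cleft_cutoff``; the total surviving-site count is
    conserved exactly across the returned edges.
    """
    surviving = sites[sites["cleft_score"] >= cleft_cutoff]
    if surviving.empty:
        return pd.DataFrame(columns=list(EDGE_COLUMNS)).astype(
            {"syn_count": np.int64})
    edges = (surviving.groupby(["pre_id", "post_id"], sort=True)
             .size().rename("syn_count").reset_index())
    return edges
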
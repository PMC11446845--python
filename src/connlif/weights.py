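"""Signed synaptic weight matrices and their edited variants.

The weight of a directed connection is
``w[j, i] = syn_count(j, i) * sign(j) * w_syn`` (mV), optionally with the
inhibitory entries rescaled by ``inh_scale`` to probe the
inhibitory:excitatory ratio. The matrix is Dale-consistent by construction:
all outgoing weights of one neuron share that neuron's sign. Edited
variants — neurons silenced by zeroing their outgoing rows, or weights
shuffled across the fixed edge set — are what the in-silico screens
consume.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .params import LIFParameters


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).values.tobytes())
    return h.hexdigest()[:16]


@dataclass
class SignedWeights:
    """Sparse directed weight matrix with its neuron-id index.

    ``matrix[j, i]`` is the weight (mV) from presynaptic neuron index ``j``
    onto postsynaptic index ``i``; ``neuron_ids[j]`` maps index to id.
    """

    matrix: sparse.csr_matrix
    neuron_ids: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = {nid: i for i, nid in enumerate(self.neuron_ids)}

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    def weight(self, pre, post) -> float:
        return float(self.matrix[self.index[pre], self.index[post]])

    def to_triplets(self) -> pd.DataFrame:
        """Long-format (pre_id, post_id, weight_mv) view of the nonzeros."""
        coo = self.matrix.tocoo()
        ids = np.asarray(self.neuron_ids, dtype=object)
        return pd.DataFrame({"pre_id": ids[coo.row], "post_id": ids[coo.col],
                             "weight_mv": coo.data})


def build_weight_matrix(edges: pd.DataFrame, signs: pd.DataFrame,
                        params: LIFParameters,
                        inh_scale: float = 1.0) -> SignedWeights:
    """Build the signed weight matrix from an edge table and a sign table.

    Parameters
    ----------
    edges : edge table with pre_id, post_id, syn_count.
    signs : sign table indexed by neuron id with a ``sign`` column
        (output of :func:`connlif.io.assign_neuron_signs`), or any mapping
        supporting ``signs["sign"]``.
    inh_scale : multiplier applied to inhibitory weights only; 1.0 keeps
        excitatory and inhibitory synapses at equal magnitude, 0.5 / 1.5
        probe the +/-50% inhibitory-ratio variants.

    Raises ``ValueError`` naming the neuron if a presynaptic id has no sign.
    """
    sign_map = signs["sign"] if isinstance(signs, pd.DataFrame) else pd.Series(signs)
    ids = sorted(set(edges["pre_id"]) | set(edges["post_id"]), key=str)
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    if len(edges):
        missing = set(edges["pre_id"]) - set(sign_map.index)
        if missing:
            raise ValueError(
                "no sign assigned for presynaptic neuron(s): "
                + ", ".join(map(str, sorted(missing, key=str)[:10])))
        pre = edges["pre_id"].map(index).to_numpy()
        post = edges["post_id"].map(index).to_numpy()
        s = edges["pre_id"].map(sign_map).to_numpy(dtype=float)
        w = edges["syn_count"].to_numpy(dtype=float) * s * params.w_syn
        w = np.where(s < 0, w * inh_scale, w)
        mat = sparse.coo_matrix((w, (pre, post)), shape=(n, n)).tocsr()
        mat.eliminate_zeros()
    else:
        mat = sparse.csr_matrix((n, n))
    meta = {"edges_hash": _hash_frame(edges) if len(edges) else "empty",
            "w_syn": params.w_syn, "inh_scale": inh_scale}
    return SignedWeights(mat, tuple(ids), meta)


def silence_neurons(w: SignedWeights, targets) -> SignedWeights:
    """Zero all outgoing weights of each target neuron.

    Incoming weights and the targets' own dynamics are untouched — this is
    the screens' "eliminate all output" silencing. Idempotent.
    """
    targets = list(targets)
    unknown = [t for t in targets if t not in w.index]
    if unknown:
        raise ValueError(f"unknown neuron id(s): {unknown}")
    mask = np.ones(w.n_neurons)
    mask[[w.index[t] for t in targets]] = 0.0
    mat = sparse.diags(mask).dot(w.matrix).tocsr()
    mat.eliminate_zeros()
    meta = dict(w.meta, silenced=tuple(map(str, targets)))
    return SignedWeights(mat, w.neuron_ids, meta)


def shuffle_weights(w: SignedWeights, seed: int,
                    method: str = "permute") -> SignedWeights:
    """Shuffle weights while preserving their global distribution.

    method="permute" (default): the multiset of signed weight values is
    randomly permuted across the existing directed edge positions, so the
    degree structure is preserved exactly. method="rewire": the same weight
    multiset is placed on freshly drawn random directed edges (no self
    loops), destroying the degree structure as well. Both may violate
    Dale's principle; the control operates on weights, not neurons.
    """
    rng = np.random.default_rng(seed)
    mat = w.matrix.tocsr(copy=True)
    data = mat.data
    if method == "permute":
        mat.data = rng.permutation(data)
    elif method == "rewire":
        n, m = w.n_neurons, len(data)
        if m > n * (n - 1):
            raise ValueError("too many edges to rewire without self-loops")
        chosen = set()
        while len(chosen) < m:
            k = m - len(chosen)
            pre = rng.integers(0, n, size=2 * k)
            post = rng.integers(0, n, size=2 * k)
            for a, b in zip(pre, post):
                if a != b and (a, b) not in chosen:
                    chosen.add((int(a), int(b)))
                    if len(chosen) == m:
                        break
        rows, cols = zip(*sorted(chosen))
        mat = sparse.coo_matrix((rng.permutation(data), (rows, cols)),
                                shape=mat.shape).tocsr()
    else:
        raise ValueError(f"unknown shuffle method {method!r}")
    meta = dict(w.meta, shuffled={"seed": int(seed), "method": method})
    return SignedWeights(mat, w.neuron_ids, meta)


def write_triplets(w: SignedWeights, path) -> None:
    w.to_triplets().to_csv(path, index=False)


def read_triplets(path) -> SignedWeights:
    df = pd.read_csv(path)
    ids = sorted(set(df["pre_id"]) | set(df["post_id"]), key=str)
    index = {nid: i for i, nid in enumerate(ids)}
    mat = sparse.coo_matrix(
        (df["weight_mv"],
         (df["pre_id"].map(index), df["post_id"].map(index))),
        shape=(len(ids), len(ids))).tocsr()
    return SignedWeights(mat, tuple(ids), {"source": str(path)})
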
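"""Sensory-modality clustering from connectivity vectors.

Sensory neurons of one organ fall into modalities (e.g. sugar- vs
water-sensing) that are visible in their synaptic targets: each source
neuron is represented by its vector of synapse counts onto a partner set,
and the vectors are clustered agglomeratively under the cosine distance
d(x, y) = 1 - x.y / (|x||y|). Cosine distance is scale-invariant, so raw
counts and per-row proportions give identical dendrograms; a binarized
variant is exposed for sensitivity checks. Two clusterings of the same
neurons (e.g. by downstream vs upstream partners) are compared with the
adjusted Rand index on their common neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score


@dataclass
class ConnectivityProfile:
    """Rows = source neurons, columns = partner neurons, entries >= 0."""
    matrix: pd.DataFrame
    direction: str = "outgoing"  # outgoing: source->partner counts


def connectivity_vectors(edges: pd.DataFrame, sources, partners,
                         direction: str = "outgoing") -> ConnectivityProfile:
    """Lift per-pair synapse counts into a sources x partners matrix.

    direction="outgoing" reads syn_count(source -> partner);
    direction="incoming" reads syn_count(partner -> source). Absent pairs
    are 0.
    """
    sources, partners = list(sources), list(partners)
    if not sources or not partners:
        raise ValueError("sources and partners must be nonempty")
    if direction not in ("outgoing", "incoming"):
        raise ValueError(f"unknown direction {direction!r}")
    a, b = ("pre_id", "post_id") if direction == "outgoing" \
        else ("post_id", "pre_id")
    sub = edges[edges[a].isin(sources) & edges[b].isin(partners)]
    mat = pd.DataFrame(0, index=pd.Index(sources, name="neuron_id"),
                       columns=partners, dtype=np.int64)
    for _, row in sub.iterrows():
        mat.loc[row[a], row[b]] += int(row["syn_count"])
    return ConnectivityProfile(mat, direction)


@dataclass
class ClusterResult:
    labels: pd.Series            # neuron_id -> cluster label (1-based)
    linkage: np.ndarray          # scipy linkage matrix
    distances: pd.DataFrame = field(repr=False, default=None)


def cosine_distances(profile: ConnectivityProfile) -> pd.DataFrame:
    """Pairwise cosine distance matrix of the profile rows."""
    X = profile.matrix.to_numpy(dtype=float)
    _check_rows(profile)
    d = squareform(pdist(X, metric="cosine"))
    ids = profile.matrix.index
    return pd.DataFrame(d, index=ids, columns=ids)


def _check_rows(profile: ConnectivityProfile) -> None:
    norms = np.linalg.norm(profile.matrix.to_numpy(dtype=float), axis=1)
    if (norms == 0).any():
        bad = list(profile.matrix.index[norms == 0])
        raise ValueError("cosine distance undefined for all-zero "
                         f"connectivity row(s): {bad}")


def cluster_modalities(profile: ConnectivityProfile, k: int | None = None,
                       height: float | None = None,
                       linkage_method: str = "average",
                       binarize: bool = False) -> ClusterResult:
    """Agglomerative clustering of connectivity rows under cosine distance.

    Exactly one of ``k`` (cluster count) or ``height`` (dendrogram cut
    distance) must be given. Labels are deterministic for fixed input.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if len(profile.matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    _check_rows(profile)
    X = profile.matrix.to_numpy(dtype=float)
    if binarize:
        X = (X > 0).astype(float)
    cond = pdist(X, metric="cosine")
    # tiny negative values can appear from floating-point cancellation
    cond = np.clip(cond, 0.0, None)
    Z = hierarchy.linkage(cond, method=linkage_method)
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(flat, index=profile.matrix.index, name="cluster")
    dist = pd.DataFrame(squareform(cond), index=profile.matrix.index,
                        columns=profile.matrix.index)
    return ClusterResult(labels, Z, dist)


def clustering_agreement(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Adjusted Rand index between two clusterings on their common neurons.

    1.0 means identical partitions (up to relabeling); ~0 means chance.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) < 2:
        raise ValueError("clusterings share fewer than two neurons")
    return float(adjusted_rand_score(labels_a.loc[common],
                                     labels_b.loc[common]))


def to_newick(result: ClusterResult) -> str:
    """Serialize the dendrogram as a newick tree with branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    names = [str(i) for i in result.labels.index]

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def write_labels(result: ClusterResult, path) -> None:
    result.labels.rename_axis("neuron_id").to_csv(path)
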
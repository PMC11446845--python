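import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import connlif as cl


@pytest.fixture(scope="session")
def params():
    return cl.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def chain():
    """Feedforward chain with planted all-excitatory pathway."""
    return cl.make_feedforward_chain(layers=(5, 3, 1), syn_count=40, seed=7)


@pytest.fixture(scope="session")
def chain_weights(chain, params):
    signs = cl.assign_neuron_signs(chain.sites)
    return cl.build_weight_matrix(chain.edges, signs, params)


@pytest.fixture(scope="session")
def single_neuron():
    """One isolated neuron, no synapses."""
    return cl.SignedWeights(sparse.csr_matrix((1, 1)), ("n0",))


#: Reduced trial settings used throughout the suite to keep runtimes short.
FAST = dict(n_trials=3, duration_ms=400.0)


def triplet_weights(triplets):
    """Build a SignedWeights directly from (pre, post, weight_mv) rows."""
    ids = sorted({t[0] for t in triplets} | {t[1] for t in triplets},
                 key=str)
    index = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    mat = sparse.lil_matrix((n, n))
    for pre, post, w in triplets:
        mat[index[pre], index[post]] += w
    return cl.SignedWeights(mat.tocsr(), tuple(ids))


def make_sites(rows):
    """Site table from (pre, post, cleft, transmitter) tuples with a
    decisive arg-max score for the named transmitter."""
    recs = []
    for pre, post, cleft, nt in rows:
        rec = {"pre_id": pre, "post_id": post, "cleft_score": cleft}
        for t in cl.NT_TYPES:
            rec[t] = 0.9 if t == nt else 0.05
        recs.append(rec)
    cols = ["pre_id", "post_id", "cleft_score"] + list(cl.NT_TYPES)
    return pd.DataFrame(recs, columns=cols)
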
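import numpy as np
import pytest

import strucnet as sn


@pytest.fixture(scope="session")
def schema83():
    return sn.default_schema()


@pytest.fixture(scope="session")
def small_schema():
    return sn.generic_schema(12)


def make_connectome(weights, schema=None, subject_id="s"):
    w = np.asarray(weights)
    if schema is None:
        schema = sn.generic_schema(w.shape[0])
    return sn.SubjectConnectome(schema, w, subject_id=subject_id)


def random_connectome(n_nodes, density, rng, max_weight=50, schema=None):
    """Random symmetric integer-weighted graph for oracle comparisons."""
    if schema is None:
        schema = sn.generic_schema(n_nodes)
    iu = np.triu_indices(n_nodes, k=1)
    w = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    present = rng.random(len(iu[0])) < density
    vals = rng.integers(1, max_weight + 1, size=len(iu[0]))
    w[iu] = np.where(present, vals, 0)
    w += w.T
    return sn.SubjectConnectome(schema, w)


@pytest.fixture(scope="session")
def null_cohort_small():
    """Exchangeable 8v8 cohort over 20 nodes (no planted effect)."""
    spec = sn.CohortSpec(n_a=8, n_b=8, n_nodes=20, density=0.3, seed=11, effect=None)
    return sn.sample_cohort(spec)
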
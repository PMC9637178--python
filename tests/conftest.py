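import numpy as np
import pytest

from petloop.core_io import PETIndex
from petloop.loopcall import call_loops
from petloop.synthetic import (
    SimConfig,
    TFSpec,
    reference_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def ref_result():
    """The reference synthetic dataset (seed 42)."""
    return simulate_dataset(reference_config())


@pytest.fixture(scope="session")
def ref_index(ref_result):
    return PETIndex.from_pets(
        ref_result.pets_a, {"chrS": ref_result.config.chrom_length}
    )


@pytest.fixture(scope="session")
def called_loops(ref_index):
    """Loops called on the reference fixture at the documented defaults."""
    return call_loops(
        ref_index, (200, 500, 1000, 2000), min_pts=10, cut=5000
    )


@pytest.fixture(scope="session")
def tf_fixture():
    """Fixture for TF enrichment: 500 loops, a planted co-binding factor and
    an anchors-independent one."""
    cfg = SimConfig(
        chrom_length=30_000_000,
        n_peaks=1200,
        n_loops=500,
        pets_per_loop=(1, 2),
        n_background_pets=0,
        tf_specs=(TFSpec("PLANTED", 0.8, 0.1), TFSpec("IND", 0.0, 0.3)),
        seed=42,
    )
    return simulate_dataset(cfg)


def naive_dbscan(x, y, eps, min_pts):
    """Brute-force O(n^2) DBSCAN oracle with scan order sorted by (x, y).

    Independent of the package implementation: full distance matrix,
    sequential cluster expansion, border points labeled by the first cluster
    that reaches them.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = x.size
    out = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return out
    order = np.lexsort((y, x))
    xs, ys = x[order].astype(float), y[order].astype(float)
    d2 = (xs[:, None] - xs[None, :]) ** 2 + (ys[:, None] - ys[None, :]) ** 2
    adj = d2 <= float(eps) ** 2
    core = adj.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=np.int64)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            p = queue.pop()
            for q in np.nonzero(adj[p])[0]:
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        queue.append(int(q))
        cid += 1
    out[order] = labels
    return out


def canonical_labels(labels):
    """Relabel cluster ids by first occurrence so partitions compare exactly."""
    mapping = {}
    out = []
    for lab in labels:
        if lab < 0:
            out.append(-1)
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return out
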
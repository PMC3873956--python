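"""Shared fixtures: a tiny hand-built ontology and a small synthetic
universe reused across test modules (session-scoped; generation is the
expensive part)."""

from __future__ import annotations

import pytest

import complexweaver as cw


@pytest.fixture()
def tiny_dag() -> cw.OntologyDAG:
    """One BP namespace: root -> {mid1, mid2}; mid1 -> {t1, t2};
    mid2 -> {t3}.  Annotation counts: t1: 3 proteins, t2: 1, t3: 1.

    Total BP annotation events = 5.
    """
    parents = {
        "root": set(),
        "mid1": {"root"},
        "mid2": {"root"},
        "t1": {"mid1"},
        "t2": {"mid1"},
        "t3": {"mid2"},
    }
    namespace = {t: "BP" for t in parents}
    annotations = {
        "A": {"t1"},
        "B": {"t1"},
        "C": {"t1"},
        "D": {"t2"},
        "E": {"t3"},
    }
    return cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)


@pytest.fixture(scope="session")
def small_universe():
    """A compact planted universe for integration-style unit tests:
    150 proteins, 8 complexes, moderate noise defaults."""
    truth = cw.generate_truth(n_proteins=150, n_complexes=8, seed=42)
    store = cw.generate_evidence(truth, seed=43)
    pool, hidden = cw.generate_pool(truth, seed=44)
    return truth, store, pool, hidden


@pytest.fixture(scope="session")
def small_features(small_universe):
    truth, store, pool, hidden = small_universe
    pairs = sorted(pool.positives | pool.unlabeled)
    feats = cw.assemble_features(pairs, store)
    binary = cw.apply_binning(feats, cw.fit_binning(feats, 5))
    return feats, binary
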
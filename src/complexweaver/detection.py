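"""Complex detection: native Markov clustering plus adapters for the
output files of external detectors.

MCL simulates random walks on the network: the column-stochastic
transition matrix is alternately expanded (matrix power, letting flow
spread) and inflated (entrywise power with column renormalization,
strengthening strong currents and weakening weak ones) until it
converges to a sparse attractor structure whose connected regions are
read off as clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core import ComplexSet
from .io_formats import _data_lines, read_complexes

logger = logging.getLogger(__name__)

__all__ = ["MCLParams", "MCLResult", "mcl_cluster", "read_external_clusters", "filter_complexes"]


@dataclass
class MCLParams:
    """Markov-clustering knobs.

    inflation > 1 controls granularity (higher = smaller clusters);
    expansion is the matrix-power exponent; self-loops of weight 1 are
    added before normalization (standard regularization that guarantees
    aperiodic walks).
    """

    inflation: float = 2.0
    expansion: int = 2
    max_iterations: int = 100
    tolerance: float = 1e-6
    prune_threshold: float = 1e-5
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class MCLResult:
    clusters: ComplexSet
    converged: bool
    iterations: int
    dropped_small: int


def _interpret(m: np.ndarray, nodes: list[str], thresh: float) -> list[set[int]]:
    """Read clusters off the converged matrix.

    Attractor rows (positive diagonal mass) define clusters as their
    column supports; attractors whose supports overlap belong to one
    attractor system; every column is assigned to the system holding
    its largest mass (lexicographic node tie-break).
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > thresh]
    if not attractors:  # fallback: every node its own attractor
        attractors = list(range(n))
    # union attractors with overlapping supports into systems
    parent = list(range(len(attractors)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    supports = [set(np.flatnonzero(m[a] > thresh)) | {a} for a in attractors]
    for i in range(len(attractors)):
        for j in range(i + 1, len(attractors)):
            if supports[i] & supports[j]:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi
    systems: dict[int, list[int]] = {}
    for i, a in enumerate(attractors):
        systems.setdefault(find(i), []).append(a)
    sys_ids = sorted(systems, key=lambda r: min(nodes[a] for a in systems[r]))
    clusters: dict[int, set[int]] = {r: set() for r in sys_ids}
    # sys_ids are in lexicographic order of their smallest node, so a
    # strict comparison gives the documented tie-break for free
    for j in range(n):
        best, best_mass = None, 0.0
        for r in sys_ids:
            mass = float(sum(m[a, j] for a in systems[r]))
            if mass > best_mass + 1e-15:
                best, best_mass = r, mass
        if best is None or best_mass <= thresh:
            continue  # no attractor mass; node dropped from clustering
        clusters[best].add(j)
    return [c for r, c in clusters.items() if c]


def mcl_cluster(network: nx.Graph, params: MCLParams | None = None) -> MCLResult:
    """Partition a network into complexes by Markov clustering.

    Works per connected component (flow never crosses components, so
    this changes nothing but saves work).  Clusters smaller than
    ``min_cluster_size`` are dropped and counted; every retained node
    sits in exactly one cluster.
    """
    if params is None:
        params = MCLParams()
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    raw_clusters: list[set[str]] = []
    converged_all = True
    total_iter = 0
    for comp in nx.connected_components(network):
        nodes = sorted(comp)
        sub = network.subgraph(comp)
        n = len(nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        m = np.zeros((n, n))
        for u, v, data in sub.edges(data=True):
            w = float(data.get("weight") or 1.0)
            m[idx[u], idx[v]] = w
            m[idx[v], idx[u]] = w
        np.fill_diagonal(m, m.diagonal() + 1.0)
        m /= m.sum(axis=0, keepdims=True)
        converged = False
        it = 0
        for it in range(1, params.max_iterations + 1):
            prev = m
            m = np.linalg.matrix_power(m, params.expansion)
            m = np.power(m, params.inflation)
            m[m < params.prune_threshold] = 0.0
            colsum = m.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            m /= colsum
            if np.max(np.abs(m - prev)) < params.tolerance:
                converged = True
                break
        total_iter += it
        if not converged:
            logger.warning(
                "MCL did not converge on a %d-node component in %d iterations",
                n, params.max_iterations,
            )
            converged_all = False
        for cl in _interpret(m, nodes, params.prune_threshold):
            raw_clusters.append({nodes[i] for i in cl})
    raw_clusters.sort(key=lambda c: min(c))
    kept = [c for c in raw_clusters if len(c) >= params.min_cluster_size]
    dropped = len(raw_clusters) - len(kept)
    if dropped:
        logger.info("dropped %d cluster(s) below size %d", dropped, params.min_cluster_size)
    return MCLResult(
        clusters=ComplexSet(kept),
        converged=converged_all,
        iterations=total_iter,
        dropped_small=dropped,
    )


def read_external_clusters(path: str | Path, format: str = "one-per-line") -> ComplexSet:
    """Adapter for external detector output.

    ``one-per-line``: whitespace-separated members per line.
    ``labeled-two-column``: ``clusterID<TAB>protein`` rows; clusters in
    first-appearance order.
    """
    if format == "one-per-line":
        return read_complexes(path)
    if format == "labeled-two-column":
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        for lineno, line in _data_lines(path):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            label, prot = parts
            if label not in groups:
                groups[label] = []
                order.append(label)
            if prot not in groups[label]:
                groups[label].append(prot)
        return ComplexSet([groups[lbl] for lbl in order], labels=order)
    raise ValueError(f"unknown format {format!r}")


def filter_complexes(complexes: ComplexSet, min_size: int = 3) -> ComplexSet:
    """Keep complexes with at least ``min_size`` members, preserving
    order (the benchmark-catalogue construction rule)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep = [i for i, c in enumerate(complexes) if len(c) >= min_size]
    return ComplexSet(
        [complexes[i] for i in keep], labels=[complexes.labels[i] for i in keep]
    )
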
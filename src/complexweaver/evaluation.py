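"""Evaluation of detected complexes and reconstructed networks.

Complex matching uses the neighborhood-affinity score
NA(p, b) = |Vp ∩ Vb|**2 / (|Vp| * |Vb|); a predicted complex p and a
reference complex b match when NA >= omega (0.25 by default, 0.20 the
common alternative).  Precision is the fraction of predicted complexes
matching at least one reference complex, recall the fraction of
reference complexes matched by at least one prediction, and F their
harmonic mean.

Functional coherence of a cluster is scored by the one-sided
hypergeometric tail of its best GO term; a network's pair relevance is
the fraction of its edges whose pair similarity (GO semantic similarity
or coexpression) exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .core import ComplexSet, OntologyDAG, NAMESPACES

__all__ = [
    "na_score",
    "MatchResult",
    "match_and_score",
    "enrichment_significance",
    "proportion_significant",
    "pair_relevance",
]


def na_score(predicted: Iterable[str], reference: Iterable[str]) -> float:
    """Neighborhood-affinity overlap of two protein sets, in [0, 1]."""
    p, b = set(predicted), set(reference)
    if not p or not b:
        raise ValueError("NA score is undefined for empty sets")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


@dataclass
class MatchResult:
    """Complex-matching outcome at one omega threshold."""

    omega: float
    precision: float
    recall: float
    f_measure: float
    n_cp: int  # predicted complexes matching >=1 reference complex
    n_cb: int  # reference complexes matched by >=1 prediction
    best_match_predicted: list[tuple[int | None, float]] = field(default_factory=list)
    best_match_reference: list[tuple[int | None, float]] = field(default_factory=list)


def match_and_score(
    predicted: ComplexSet, reference: ComplexSet, omega: float = 0.25
) -> MatchResult:
    """Match predicted against reference complexes at threshold omega.

    Best matches are reported by maximum NA (lexicographic index
    tie-break); the precision/recall counts use only the NA >= omega
    predicate, so tie-breaking never affects them.
    """
    if len(predicted) == 0 or len(reference) == 0:
        raise ValueError("both complex sets must be non-empty")
    if not (0 < omega <= 1):
        raise ValueError("omega must be in (0, 1]")
    best_p: list[tuple[int | None, float]] = [(None, 0.0)] * len(predicted)
    best_b: list[tuple[int | None, float]] = [(None, 0.0)] * len(reference)
    n_cp = 0
    matched_b = [False] * len(reference)
    for i, p in enumerate(predicted):
        hit = False
        for j, b in enumerate(reference):
            na = na_score(p, b)
            if na > best_p[i][1]:
                best_p[i] = (j, na)
            if na > best_b[j][1]:
                best_b[j] = (i, na)
            if na >= omega:
                hit = True
                matched_b[j] = True
        if hit:
            n_cp += 1
    n_cb = sum(matched_b)
    precision = n_cp / len(predicted)
    recall = n_cb / len(reference)
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchResult(
        omega=omega,
        precision=precision,
        recall=recall,
        f_measure=f,
        n_cp=n_cp,
        n_cb=n_cb,
        best_match_predicted=best_p,
        best_match_reference=best_b,
    )


def enrichment_significance(
    cluster: Iterable[str],
    annotations: Mapping[str, set[str]],
    background: Iterable[str],
    dag: OntologyDAG | None = None,
    namespace: str | None = None,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> tuple[float, bool]:
    """Minimum hypergeometric enrichment p-value of a cluster.

    For each term annotating at least one cluster member, the p-value
    is the one-sided tail P(X >= k) with k = cluster members annotated,
    K = background proteins annotated, n = cluster size, N = background
    size.  Returns (min p over terms, p < alpha).  ``bonferroni=True``
    multiplies by the number of tested terms (capped at 1) before
    thresholding.  Restrict to one namespace by passing the ontology
    and a namespace name.
    """
    cluster = set(cluster)
    bg = set(background)
    missing = cluster - bg
    if missing:
        raise ValueError(f"cluster proteins outside background: {sorted(missing)}")

    def terms_of(prot: str) -> set[str]:
        ts = annotations.get(prot, set())
        if dag is not None and namespace is not None:
            ts = {t for t in ts if dag.namespace[t] == namespace}
        return ts

    candidate_terms: set[str] = set()
    for prot in cluster:
        candidate_terms |= terms_of(prot)
    if not candidate_terms:
        return 1.0, False
    n_bg = len(bg)
    n_cl = len(cluster)
    best = 1.0
    for term in sorted(candidate_terms):
        k_bg = sum(1 for prot in bg if term in terms_of(prot))
        k_cl = sum(1 for prot in cluster if term in terms_of(prot))
        p = float(hypergeom.sf(k_cl - 1, n_bg, k_bg, n_cl))
        best = min(best, p)
    if bonferroni:
        best = min(best * len(candidate_terms), 1.0)
    return best, best < alpha


def proportion_significant(
    clusters: ComplexSet,
    annotations: Mapping[str, set[str]],
    background: Iterable[str],
    dag: OntologyDAG | None = None,
    namespace: str | None = None,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> float:
    """Fraction of clusters whose minimum enrichment p-value is below
    alpha (per namespace when a namespace is given)."""
    if len(clusters) == 0:
        raise ValueError("no clusters to evaluate")
    bg = set(background)
    hits = 0
    for cluster in clusters:
        _, sig = enrichment_significance(
            cluster, annotations, bg, dag=dag, namespace=namespace,
            alpha=alpha, bonferroni=bonferroni,
        )
        hits += sig
    return hits / len(clusters)


def pair_relevance(
    network: nx.Graph,
    pair_metric: Callable[[str, str], float | None],
    threshold: float = 0.5,
) -> tuple[float, int]:
    """Fraction of network edges whose pair metric is strictly above
    the threshold, among edges where the metric is defined.

    Returns (proportion, number of excluded edges).  Raises if no edge
    has the metric at all.
    """
    above = scored = excluded = 0
    for u, v in network.edges():
        val = pair_metric(u, v)
        if val is None:
            excluded += 1
            continue
        scored += 1
        if val > threshold:
            above += 1
    if scored == 0:
        raise ValueError("pair metric is undefined on every edge")
    return above / scored, excluded
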
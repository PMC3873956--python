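"""Core domain containers shared by every pipeline stage.

Protein pairs are plain 2-tuples of protein-ID strings held in canonical
(lexicographic) order, so that a pair can key dictionaries and DataFrame
indexes regardless of the order the two proteins appeared in on disk.
Networks are :class:`networkx.Graph` instances (undirected, at most one
edge per pair, no self-loops by construction of the readers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "canonical_pair",
    "ComplexSet",
    "OntologyDAG",
    "NAMESPACES",
]

NAMESPACES = ("BP", "CC", "MF")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered protein pair (a, b) in canonical order.

    Raises ``ValueError`` for self-pairs: a protein cannot interact with
    itself in the pairwise-evidence model used here.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class ComplexSet:
    """An ordered collection of protein complexes (protein-ID sets).

    Holds either predicted clusters or a reference catalogue.  Order is
    meaningful (file order / detection order); labels are optional and
    let duplicated member sets coexist.
    """

    def __init__(
        self,
        complexes: Iterable[Iterable[str]] = (),
        labels: Iterable[str] | None = None,
    ) -> None:
        self.complexes: list[frozenset[str]] = [frozenset(c) for c in complexes]
        if any(not c for c in self.complexes):
            raise ValueError("empty complex not allowed")
        if labels is None:
            self.labels: list[str | None] = [None] * len(self.complexes)
        else:
            self.labels = list(labels)
            if len(self.labels) != len(self.complexes):
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self.complexes == other.complexes

    def __repr__(self) -> str:
        return f"ComplexSet({len(self)} complexes)"

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]


@dataclass
class OntologyDAG:
    """A term DAG (is_a links) with per-namespace roots plus a protein
    annotation table.

    ``parents`` maps a term to its direct is_a parents (empty set for a
    namespace root).  ``namespace`` assigns each term to exactly one of
    BP / CC / MF; parent links never cross namespaces.  ``annotations``
    maps protein -> set of directly annotated terms.
    """

    parents: dict[str, set[str]] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for term, ps in self.parents.items():
            if term not in self.namespace:
                raise ValueError(f"term {term!r} has no namespace")
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {term!r} is not a term")
                if self.namespace[p] != self.namespace[term]:
                    raise ValueError(
                        f"is_a link {term!r}->{p!r} crosses namespaces"
                    )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        bad = sorted(
            t
            for terms in self.annotations.values()
            for t in terms
            if t not in self.parents
        )
        if bad:
            raise ValueError(f"annotations reference unknown terms: {bad}")

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph over all terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for term, ps in self.parents.items():
            for p in ps:
                g.add_edge(term, p)
        return g

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def roots(self, namespace: str | None = None) -> set[str]:
        out = {t for t, ps in self.parents.items() if not ps}
        if namespace is not None:
            out = {t for t in out if self.namespace[t] == namespace}
        return out

    def ancestors(self, term: str, inclusive: bool = True) -> set[str]:
        """All terms reachable from ``term`` via is_a links."""
        seen: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents[t])
        if inclusive:
            seen.add(term)
        return seen

    def descendants(self, term: str, inclusive: bool = True) -> set[str]:
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        seen: set[str] = set()
        stack = list(children[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(children[t])
        if inclusive:
            seen.add(term)
        return seen

    def annotations_in(self, protein: str, namespace: str) -> set[str]:
        return {
            t
            for t in self.annotations.get(protein, ())
            if self.namespace[t] == namespace
        }
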
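"""Readers and writers for the repository's on-disk dialects.

Every file is plain TSV with ``#`` comment lines.  Dialects:

* edge list           ``p1<TAB>p2[<TAB>weight]``
* pair scores         ``p1<TAB>p2<TAB>score``
* complexes           one complex per line, whitespace-separated IDs
* ontology terms      ``term<TAB>namespace<TAB>parent1,parent2,...``
* annotations         ``protein<TAB>term``
* expression          header row of sample IDs, one gene per row
* domains             ``protein<TAB>domain``
* DDI confidences     ``domain1<TAB>domain2<TAB>confidence``

Duplicate pair entries keep the maximum weight/score (scores are
confidences, so max is the conservative union of evidence); self-loops
are dropped and counted in the log.  Writers emit exactly what the
readers accept, so write -> read is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .core import NAMESPACES, ComplexSet, OntologyDAG, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_pair_scores",
    "write_pair_scores",
    "read_complexes",
    "write_complexes",
    "read_ontology",
    "write_ontology",
    "read_annotations",
    "write_annotations",
    "read_expression",
    "write_expression",
    "read_domains",
    "write_domains",
    "read_ddi",
    "write_ddi",
    "read_term_list",
    "write_term_list",
    "write_ranked_pairs",
    "read_ranked_pairs",
    "ParseError",
]


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, has_weight: bool = False) -> nx.Graph:
    """Read a 2- or 3-column edge list into an undirected graph.

    Pairs are canonicalized; duplicate lines collapse keeping the max
    weight; self-loops are dropped (count logged).
    """
    g = nx.Graph()
    dropped = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        want = 3 if has_weight else 2
        if len(parts) != want:
            raise ParseError(
                f"{path}:{lineno}: expected {want} columns, got {len(parts)}"
            )
        a, b = parts[0], parts[1]
        if has_weight:
            try:
                w = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
        else:
            w = None
        if a == b:
            dropped += 1
            continue
        u, v = canonical_pair(a, b)
        if w is None:
            g.add_edge(u, v)
        elif g.has_edge(u, v):
            old = g[u][v].get("weight")
            g[u][v]["weight"] = w if old is None else max(old, w)
        else:
            g.add_edge(u, v, weight=w)
    if dropped:
        logger.warning("dropped %d self-loop line(s) from %s", dropped, path)
    return g


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(network.edges(data=True)):
            a, b = canonical_pair(u, v)
            w = data.get("weight")
            if w is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{w:g}\n")


def read_pair_scores(path: str | Path) -> dict[tuple[str, str], float]:
    """Read ``p1<TAB>p2<TAB>score`` into a canonical-pair keyed mapping."""
    scores: dict[tuple[str, str], float] = {}
    dropped = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            s = float(parts[2])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric score {parts[2]!r}"
            ) from None
        if parts[0] == parts[1]:
            dropped += 1
            continue
        key = canonical_pair(parts[0], parts[1])
        scores[key] = max(scores.get(key, float("-inf")), s)
    if dropped:
        logger.warning("dropped %d self-pair line(s) from %s", dropped, path)
    return scores


def write_pair_scores(
    scores: Mapping[tuple[str, str], float], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for (a, b), s in sorted(scores.items()):
            fh.write(f"{a}\t{b}\t{s:g}\n")


def read_complexes(path: str | Path) -> ComplexSet:
    """One complex per line; within-line duplicate IDs removed; empty
    lines skipped with a warning."""
    complexes: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            members = list(dict.fromkeys(line.split()))
            complexes.append(members)
    return ComplexSet(complexes)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c)) + "\n")


def read_term_list(path: str | Path) -> set[str]:
    """One term ID per line (a GO Slim list)."""
    terms: set[str] = set()
    for _, line in _data_lines(path):
        terms.add(line.strip())
    return terms


def write_term_list(terms: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(terms):
            fh.write(t + "\n")


def read_ontology(terms_path: str | Path, annot_path: str | Path) -> OntologyDAG:
    """Read the term table and the annotation table into an OntologyDAG.

    Raises on cycles, cross-namespace links, unknown namespaces, and
    annotations referencing unknown terms (offenders listed).
    """
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for lineno, line in _data_lines(terms_path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{terms_path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        term, ns, parent_field = parts
        if ns not in NAMESPACES:
            raise ParseError(
                f"{terms_path}:{lineno}: unknown namespace {ns!r}"
            )
        parents[term] = (
            {p for p in parent_field.split(",") if p} if parent_field else set()
        )
        namespace[term] = ns
    annotations = read_annotations(annot_path)
    return OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)


def write_ontology(dag: OntologyDAG, terms_path: str | Path, annot_path: str | Path) -> None:
    with open(terms_path, "w") as fh:
        for term in sorted(dag.parents):
            ps = ",".join(sorted(dag.parents[term]))
            fh.write(f"{term}\t{dag.namespace[term]}\t{ps}\n")
    write_annotations(dag.annotations, annot_path)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    annotations: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        annotations.setdefault(parts[0], set()).add(parts[1])
    return annotations


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in sorted(annotations):
            for term in sorted(annotations[prot]):
                fh.write(f"{prot}\t{term}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; header row of sample IDs; 'NA' = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = None
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_domains(path: str | Path) -> dict[str, set[str]]:
    """``protein<TAB>domain`` table -> protein -> set of domains."""
    out: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_domains(domains: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in sorted(domains):
            for d in sorted(domains[prot]):
                fh.write(f"{prot}\t{d}\n")


def read_ddi(path: str | Path) -> dict[frozenset[str], float]:
    """Domain-domain interaction confidences, symmetric in the two
    domain columns (keyed by the unordered domain pair; d-d self pairs
    allowed).  Duplicates keep max."""
    out: dict[frozenset[str], float] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            c = float(parts[2])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric confidence {parts[2]!r}"
            ) from None
        key = frozenset((parts[0], parts[1]))
        out[key] = max(out.get(key, float("-inf")), c)
    return out


def write_ddi(ddi: Mapping[frozenset[str], float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(ddi, key=lambda k: sorted(k)):
            ds = sorted(key)
            d1, d2 = (ds[0], ds[0]) if len(ds) == 1 else (ds[0], ds[1])
            fh.write(f"{d1}\t{d2}\t{ddi[key]:g}\n")


def write_ranked_pairs(
    ranked: Iterable[tuple[tuple[str, str], float]], path: str | Path
) -> None:
    """``p1<TAB>p2<TAB>aggregate_score<TAB>rank`` (rank starts at 1)."""
    with open(path, "w") as fh:
        for rank, ((a, b), score) in enumerate(ranked, start=1):
            fh.write(f"{a}\t{b}\t{score:.10g}\t{rank}\n")


def read_ranked_pairs(path: str | Path) -> list[tuple[tuple[str, str], float]]:
    out: list[tuple[tuple[str, str], float]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
            )
        out.append((canonical_pair(parts[0], parts[1]), float(parts[2])))
    return out
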
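"""Per-pair evidence features from six source families.

A candidate protein pair is described by:

* six GO features — for each namespace (BP, CC, MF) a binary GO Slim
  overlap (Type I) and an information-content semantic similarity
  (Type II, Resnik/Lord most-informative-common-ancestor, normalized
  to [0, 1]);
* one gene-coexpression feature (Pearson r of log-expression profiles);
* one domain-domain interaction score (sum of DDI confidences over all
  domain pairs of the two proteins);
* passthrough confidence columns (a STRING-style score plus any number
  of AP-MS reliability scores);
* one Czekanowski-Dice neighbor-overlap score computed on an observed
  interaction network.

Feature absence is first-class: "no domain data" is recorded as NaN and
is distinct from "domain data present, score 0".  Discretization turns
each feature into equal-frequency one-hot bins plus an explicit absent
indicator, so downstream learners see the distinction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import NAMESPACES, OntologyDAG, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "TermStats",
    "term_probability",
    "term_similarity",
    "gene_go_similarity",
    "goslim_overlap",
    "coexpression",
    "ddi_score",
    "cd_distance_feature",
    "EvidenceStore",
    "FeatureSchema",
    "assemble_features",
    "filter_pairs",
    "BinningSpec",
    "fit_binning",
    "apply_binning",
]


# ---------------------------------------------------------------------------
# GO information content


class TermStats:
    """Annotation-frequency statistics for one namespace of an ontology.

    For a term t, the closure count is the number of protein->term
    annotation events landing on t or any of its descendants; the term
    probability p(t) is that count divided by the total number of
    annotation events in the namespace.  p is 1 at the namespace root
    and non-decreasing from child to parent.  Terms whose closure count
    is zero get the Laplace-smoothed p = 1/(total+1) so their
    information content -ln p stays finite.
    """

    def __init__(self, dag: OntologyDAG, namespace: str) -> None:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        self.namespace = namespace
        self._dag = dag
        ns_terms = {t for t in dag.parents if dag.namespace[t] == namespace}
        direct: dict[str, int] = {t: 0 for t in ns_terms}
        total = 0
        for terms in dag.annotations.values():
            for t in terms:
                if t in direct:
                    direct[t] += 1
                    total += 1
        self.total = total
        # closure count via reverse-topological accumulation
        order = list(nx.topological_sort(dag.graph()))  # children first? no
        # graph edges are child -> parent, so topological order puts a
        # child before its parents; accumulate by walking that order and
        # pushing counts up is wrong (double counts diamonds).  Use the
        # definition directly: closure(t) = sum of direct counts over
        # descendants(t) inclusive; memoize descendant sets bottom-up.
        del order
        children: dict[str, set[str]] = {t: set() for t in ns_terms}
        for t in ns_terms:
            for p in dag.parents[t]:
                children[p].add(t)
        closure_sets: dict[str, frozenset[str]] = {}
        order2 = [
            t
            for t in nx.topological_sort(dag.graph().reverse())
            if t in ns_terms
        ]
        # reversed graph: parent -> child; topological order puts a parent
        # before its children, so iterate reversed to do leaves first
        for t in reversed(order2):
            s = {t}
            for c in children[t]:
                s |= closure_sets[c]
            closure_sets[t] = frozenset(s)
        self.closure_count: dict[str, int] = {
            t: sum(direct[u] for u in closure_sets[t]) for t in ns_terms
        }
        self._p: dict[str, float] = {}
        for t in ns_terms:
            cc = self.closure_count[t]
            if total == 0 or cc == 0:
                self._p[t] = 1.0 / (total + 1)
            else:
                self._p[t] = cc / total

    def p(self, term: str) -> float:
        return self._p[term]

    def ic(self, term: str) -> float:
        """Information content -ln p(term)."""
        return -math.log(self._p[term])

    @property
    def max_ic(self) -> float:
        """Normalization constant: the IC of a single-annotation term,
        -ln(1/total)."""
        return math.log(self.total) if self.total > 1 else 0.0


def _stats(dag: OntologyDAG, namespace: str, stats: TermStats | None) -> TermStats:
    if stats is not None:
        if stats.namespace != namespace:
            raise ValueError("stats namespace mismatch")
        return stats
    return TermStats(dag, namespace)


def term_probability(
    term: str, dag: OntologyDAG, namespace: str, stats: TermStats | None = None
) -> float:
    """Annotation probability p(t) of a term within its namespace."""
    st = _stats(dag, namespace, stats)
    if dag.namespace[term] != namespace:
        raise ValueError(f"term {term!r} is not in namespace {namespace}")
    return st.p(term)


def term_similarity(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    namespace: str,
    stats: TermStats | None = None,
    normalized: bool = True,
) -> float:
    """Semantic similarity of two terms: information content of the
    most informative common ancestor, normalized to [0, 1] by the
    corpus maximum IC.

    ``normalized=False`` returns the raw -ln p of the best common
    ancestor.  Symmetric; 0 when the only common ancestor is the root.
    """
    if dag.namespace[t1] != namespace or dag.namespace[t2] != namespace:
        raise ValueError("terms must both belong to the requested namespace")
    st = _stats(dag, namespace, stats)
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if not common:
        return 0.0
    best = max(st.ic(t) for t in common)
    if best <= 0.0:
        return 0.0
    if not normalized:
        return best
    if st.max_ic == 0.0:
        return 0.0
    return min(best / st.max_ic, 1.0)


def gene_go_similarity(
    prot_a: str,
    prot_b: str,
    dag: OntologyDAG,
    namespace: str,
    stats: TermStats | None = None,
) -> float | None:
    """Highest term similarity over all annotation pairs of the two
    proteins in one namespace; None if either protein is unannotated
    there."""
    ta = dag.annotations_in(prot_a, namespace)
    tb = dag.annotations_in(prot_b, namespace)
    if not ta or not tb:
        return None
    st = _stats(dag, namespace, stats)
    return max(
        term_similarity(x, y, dag, namespace, stats=st) for x in ta for y in tb
    )


def goslim_overlap(
    prot_a: str,
    prot_b: str,
    slim_terms: set[str],
    namespace: str,
    dag: OntologyDAG,
) -> int | None:
    """Binary Type-I GO feature: 1 iff the slim-mapped annotation sets
    of the two proteins share a non-root term.

    Each direct annotation maps to every slim term among its ancestors
    (itself included when it is a slim term) — map2slim semantics.
    Namespace roots are removed before intersecting.  None (absent) if
    either protein has no annotation in this namespace.  Slim terms of
    other namespaces are ignored; slim terms unknown to the DAG raise.
    """
    unknown = {t for t in slim_terms if t not in dag.namespace}
    if unknown:
        raise ValueError(f"slim terms not in the ontology: {sorted(unknown)}")
    slim_terms = {t for t in slim_terms if dag.namespace[t] == namespace}
    ta = dag.annotations_in(prot_a, namespace)
    tb = dag.annotations_in(prot_b, namespace)
    if not ta or not tb:
        return None
    roots = dag.roots(namespace)

    def slim_map(terms: set[str]) -> set[str]:
        mapped: set[str] = set()
        for t in terms:
            mapped |= dag.ancestors(t) & slim_terms
        return mapped - roots

    return int(bool(slim_map(ta) & slim_map(tb)))


# ---------------------------------------------------------------------------
# expression / domains / topology


def coexpression(
    gene_a: str, gene_b: str, expr: pd.DataFrame, min_samples: int = 3
) -> float | None:
    """Pearson correlation of two (log-scale) expression profiles over
    their jointly observed samples; None if fewer than ``min_samples``
    common samples or either profile has zero variance."""
    if gene_a not in expr.index or gene_b not in expr.index:
        return None
    xa = expr.loc[gene_a].to_numpy(dtype=float)
    xb = expr.loc[gene_b].to_numpy(dtype=float)
    mask = np.isfinite(xa) & np.isfinite(xb)
    if mask.sum() < min_samples:
        return None
    xa, xb = xa[mask], xb[mask]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return None
    r = float(np.corrcoef(xa, xb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def ddi_score(
    prot_a: str,
    prot_b: str,
    domains: Mapping[str, set[str]],
    ddi: Mapping[frozenset[str], float],
) -> float:
    """Sum of DDI confidences over all (domain of A, domain of B)
    pairs; missing table entries contribute 0, proteins without domain
    data score 0."""
    da = domains.get(prot_a, set())
    db = domains.get(prot_b, set())
    total = 0.0
    for x in da:
        for y in db:
            total += ddi.get(frozenset((x, y)), 0.0)
    return total


def cd_distance_feature(
    network: nx.Graph, x: str, y: str
) -> float | None:
    """Self-inclusive Dice overlap of the two proteins' neighborhoods:
    2|N*(X) ∩ N*(Y)| / (|N*(X)| + |N*(Y)|) with N*(V) = N(V) ∪ {V}.

    Higher means the pair shares more interaction partners, hence a
    more reliable candidate interaction.  The Czekanowski-Dice
    *distance* is 1 minus this value.  None if either protein is not a
    node of the network.
    """
    if x not in network or y not in network:
        return None
    nx_set = set(network.neighbors(x)) | {x}
    ny_set = set(network.neighbors(y)) | {y}
    return 2.0 * len(nx_set & ny_set) / (len(nx_set) + len(ny_set))


# ---------------------------------------------------------------------------
# evidence store, schema, assembly


@dataclass
class EvidenceStore:
    """The six evidence-source tables the feature assembler draws from."""

    ontology: OntologyDAG | None = None
    slim_terms: set[str] = field(default_factory=set)
    expression: pd.DataFrame | None = None
    domains: dict[str, set[str]] = field(default_factory=dict)
    ddi: dict[frozenset[str], float] = field(default_factory=dict)
    score_columns: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    observed_network: nx.Graph | None = None


@dataclass(frozen=True)
class FeatureSchema:
    """Named feature slots: six GO slots, coexpression, DDI, the
    passthrough score columns, and the CD neighbor-overlap slot."""

    score_columns: tuple[str, ...] = ("string",)

    @property
    def go_features(self) -> tuple[str, ...]:
        return tuple(f"go_type1_{ns.lower()}" for ns in NAMESPACES) + tuple(
            f"go_type2_{ns.lower()}" for ns in NAMESPACES
        )

    @property
    def names(self) -> tuple[str, ...]:
        return (
            self.go_features
            + ("coexpression", "ddi")
            + self.score_columns
            + ("cd_distance",)
        )

    @classmethod
    def from_store(cls, store: EvidenceStore) -> "FeatureSchema":
        return cls(score_columns=tuple(sorted(store.score_columns)))


def assemble_features(
    pairs: Iterable[tuple[str, str]],
    store: EvidenceStore,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Build the pairs x features matrix (NaN marks an absent value).

    Deterministic given the store; row order follows the input pair
    order; pairs are canonicalized.
    """
    if schema is None:
        schema = FeatureSchema.from_store(store)
    for col in schema.score_columns:
        if col not in store.score_columns:
            raise ValueError(f"schema names missing evidence table {col!r}")
    pair_list = [canonical_pair(a, b) for a, b in pairs]
    n = len(pair_list)
    data: dict[str, np.ndarray] = {
        name: np.full(n, np.nan) for name in schema.names
    }

    dag = store.ontology
    stats = {}
    if dag is not None:
        for ns in NAMESPACES:
            stats[ns] = TermStats(dag, ns)
        sim_cache: dict[tuple[str, str, str], float] = {}

        def pair_go(prot_a, prot_b, ns):
            ta = dag.annotations_in(prot_a, ns)
            tb = dag.annotations_in(prot_b, ns)
            if not ta or not tb:
                return None
            best = 0.0
            for x in ta:
                for y in tb:
                    key = (x, y, ns) if x <= y else (y, x, ns)
                    v = sim_cache.get(key)
                    if v is None:
                        v = term_similarity(x, y, dag, ns, stats=stats[ns])
                        sim_cache[key] = v
                    if v > best:
                        best = v
            return best

    expr = store.expression
    expr_z = None
    if expr is not None and not expr.isna().any().any():
        # fast path: standardized rows, r = mean of products
        vals = expr.to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (vals - mu) / sd
        expr_z = {g: z[i] for i, g in enumerate(expr.index)}
        expr_ok = {g: sd[i, 0] > 0 for i, g in enumerate(expr.index)}

    net = store.observed_network
    nbrs: dict[str, set[str]] = {}
    if net is not None:
        nbrs = {v: set(net.neighbors(v)) | {v} for v in net}

    for i, (a, b) in enumerate(pair_list):
        if dag is not None:
            for ns in NAMESPACES:
                v1 = goslim_overlap(a, b, store.slim_terms, ns, dag)
                if v1 is not None:
                    data[f"go_type1_{ns.lower()}"][i] = v1
                v2 = pair_go(a, b, ns)
                if v2 is not None:
                    data[f"go_type2_{ns.lower()}"][i] = v2
        if expr is not None:
            if expr_z is not None:
                za = expr_z.get(a)
                zb = expr_z.get(b)
                if za is not None and zb is not None and expr_ok[a] and expr_ok[b]:
                    data["coexpression"][i] = float(
                        np.clip(np.mean(za * zb), -1.0, 1.0)
                    )
            else:
                r = coexpression(a, b, expr)
                if r is not None:
                    data["coexpression"][i] = r
        if a in store.domains and b in store.domains:
            data["ddi"][i] = ddi_score(a, b, store.domains, store.ddi)
        for col in schema.score_columns:
            v = store.score_columns[col].get((a, b))
            if v is not None:
                data[col][i] = v
        if net is not None and a in nbrs and b in nbrs:
            sa, sb = nbrs[a], nbrs[b]
            data["cd_distance"][i] = 2.0 * len(sa & sb) / (len(sa) + len(sb))

    idx = pd.MultiIndex.from_tuples(pair_list, names=["p1", "p2"])
    return pd.DataFrame(data, index=idx, columns=list(schema.names))


# ---------------------------------------------------------------------------
# filtering heuristics


def filter_pairs(
    features: pd.DataFrame,
    type2_threshold: float = 0.002,
    pearson_threshold: float = 0.5,
) -> pd.Index:
    """Drop pairs whose only evidence is weak GO + expression signal.

    A pair is removed iff all three hold:

    (i)   no DDI, passthrough-score, or neighbor-overlap evidence is
          present;
    (ii)  the BP and CC Type I features are 0 (or absent) and the BP
          and CC Type II features are below ``type2_threshold`` (or
          absent);
    (iii) the coexpression r is below ``pearson_threshold`` (or absent).

    Returns the retained row index.  MF is deliberately not inspected
    by (ii).
    """
    other_cols = [
        c
        for c in features.columns
        if c not in (
            "go_type1_bp", "go_type1_cc", "go_type1_mf",
            "go_type2_bp", "go_type2_cc", "go_type2_mf",
            "coexpression",
        )
    ]
    no_other = features[other_cols].isna().all(axis=1)

    def weak_or_absent(col: str, pred) -> pd.Series:
        v = features[col]
        return v.isna() | pred(v)

    weak_go = (
        weak_or_absent("go_type1_bp", lambda v: v == 0)
        & weak_or_absent("go_type1_cc", lambda v: v == 0)
        & weak_or_absent("go_type2_bp", lambda v: v < type2_threshold)
        & weak_or_absent("go_type2_cc", lambda v: v < type2_threshold)
    )
    weak_expr = weak_or_absent("coexpression", lambda v: v < pearson_threshold)
    removed = no_other & weak_go & weak_expr
    logger.info("filter_pairs removed %d of %d pairs", int(removed.sum()), len(features))
    return features.index[~removed]


# ---------------------------------------------------------------------------
# equal-frequency discretization


@dataclass
class BinningSpec:
    """Per-feature interior cut points for equal-frequency binning.

    A feature with boundaries [c1 < c2 < ... < c_{k-1}] expands to k
    one-hot bin columns plus one absent-indicator column.
    """

    boundaries: dict[str, np.ndarray]

    def n_bins(self, feature: str) -> int:
        return len(self.boundaries[feature]) + 1

    @property
    def total_length(self) -> int:
        return sum(self.n_bins(f) + 1 for f in self.boundaries)


def fit_binning(
    features: pd.DataFrame, bins_per_feature: int | Mapping[str, int] = 5
) -> BinningSpec:
    """Choose approximately equal-frequency cut points per feature from
    the finite values only; ties collapse to unique boundaries.  A
    feature with fewer than 2 distinct values gets a single bin (with a
    warning)."""
    boundaries: dict[str, np.ndarray] = {}
    for col in features.columns:
        k = (
            bins_per_feature
            if isinstance(bins_per_feature, int)
            else bins_per_feature[col]
        )
        if k < 1:
            raise ValueError(f"bins_per_feature must be >= 1 for {col!r}")
        v = features[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if np.unique(v).size < 2:
            logger.warning("feature %r has <2 distinct values; single bin", col)
            boundaries[col] = np.empty(0)
            continue
        qs = np.quantile(v, np.arange(1, k) / k)
        cuts = np.unique(qs)
        # drop cuts outside the open value range (all mass on one side)
        cuts = cuts[(cuts > v.min()) & (cuts < v.max())]
        boundaries[col] = cuts
    return BinningSpec(boundaries=boundaries)


def apply_binning(features: pd.DataFrame, spec: BinningSpec) -> pd.DataFrame:
    """Expand each feature to one-hot equal-frequency bins plus an
    absent indicator; exactly one column per feature is 1 in every row."""
    cols: dict[str, np.ndarray] = {}
    n = len(features)
    for col in features.columns:
        if col not in spec.boundaries:
            raise ValueError(f"binning spec lacks feature {col!r}")
        cuts = spec.boundaries[col]
        k = len(cuts) + 1
        v = features[col].to_numpy(dtype=float)
        present = np.isfinite(v)
        idx = np.searchsorted(cuts, v[present], side="right")
        onehot = np.zeros((n, k), dtype=np.int8)
        rows = np.flatnonzero(present)
        onehot[rows, idx] = 1
        for j in range(k):
            cols[f"{col}|bin{j}"] = onehot[:, j]
        cols[f"{col}|absent"] = (~present).astype(np.int8)
    return pd.DataFrame(cols, index=features.index)
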
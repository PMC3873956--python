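"""Synthetic evidence universe with planted complexes.

Generates, from a seed, the full set of inputs the pipeline consumes:
a protein universe with disjoint planted complexes; a ground-truth
interaction set (dense within complexes, sparse background); and the
six evidence sources — an ontology whose leaf terms annotate complexes
coherently, a gene-expression matrix where complex members share a
latent profile, domain assignments with a DDI confidence table,
STRING-style and AP-MS-style per-pair score columns, and a noisy
observed interaction network (false negatives removed, false positives
added) that drives the neighbor-overlap feature.

Every generator is bit-reproducible given its parameters and seed.
Default dimensions are desk-scale: 500 proteins, 20 complexes of 4-8
members, background pair probability 5e-4 (matching the sparsity of
real interactomes, where well under 1% of random pairs interact).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .core import ComplexSet, OntologyDAG, canonical_pair
from .features import EvidenceStore
from .lpu import LabeledPool

__all__ = [
    "SyntheticTruth",
    "NoiseSpec",
    "generate_truth",
    "generate_evidence",
    "generate_pool",
    "strong_signal_universe",
]


@dataclass
class SyntheticTruth:
    proteins: list[str]
    complexes: ComplexSet
    true_ppis: set[tuple[str, str]]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def candidate_pairs(self) -> list[tuple[str, str]]:
        return [canonical_pair(a, b) for a, b in itertools.combinations(self.proteins, 2)]


@dataclass
class NoiseSpec:
    """Per-source signal/noise parameters for evidence generation."""

    n_samples: int = 20           # expression arrays
    expr_noise_sd: float = 0.5    # around the unit-variance latent profile
    annotation_prob: float = 0.85  # member annotated with its complex term
    background_annotation_prob: float = 0.7
    domain_coverage: float = 0.8  # proteins with any domain data
    domain_pair_prob: float = 0.5  # true PPI gets an interacting domain pair
    score_true_mean: float = 0.8
    score_false_mean: float = 0.2
    score_sd: float = 0.25
    score_true_coverage: float = 0.8   # true PPIs present in a score column
    score_false_ratio: float = 1.0     # false entries per true entry
    apms_columns: int = 3
    observed_fn_rate: float = 0.2      # true edges missing from observed net
    observed_fp_ratio: float = 0.15    # spurious edges per true edge


def generate_truth(
    n_proteins: int = 500,
    n_complexes: int = 20,
    size_range: tuple[int, int] = (4, 8),
    within_p: float = 0.9,
    between_p: float = 5e-4,
    seed: int = 0,
) -> SyntheticTruth:
    """Plant disjoint complexes and sample the true interaction set.

    Complex sizes are uniform in ``size_range``; each within-complex
    pair is a true PPI with probability ``within_p``, each
    between-complex (or background) pair with probability ``between_p``.
    """
    if not (0 <= between_p < within_p <= 1):
        raise ValueError("need 0 <= between_p < within_p <= 1")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_complexes)
    if sizes.sum() > n_proteins:
        raise ValueError(
            f"complexes need {sizes.sum()} proteins but universe has {n_proteins}"
        )
    width = len(str(n_proteins - 1))
    proteins = [f"P{i:0{width}d}" for i in range(n_proteins)]
    order = rng.permutation(n_proteins)
    complexes: list[set[str]] = []
    pos = 0
    for s in sizes:
        complexes.append({proteins[i] for i in order[pos : pos + s]})
        pos += int(s)
    member_of: dict[str, int] = {}
    for ci, c in enumerate(complexes):
        for p in c:
            member_of[p] = ci
    true_ppis: set[tuple[str, str]] = set()
    for c in complexes:
        for a, b in itertools.combinations(sorted(c), 2):
            if rng.random() < within_p:
                true_ppis.add(canonical_pair(a, b))
    # background pairs: draw the count, then sample distinct pairs
    n_within = sum(len(c) * (len(c) - 1) // 2 for c in complexes)
    n_total = n_proteins * (n_proteins - 1) // 2
    n_between = n_total - n_within
    n_bg = rng.binomial(n_between, between_p)
    bg: set[tuple[str, str]] = set()
    while len(bg) < n_bg:
        i, j = rng.integers(0, n_proteins, size=2)
        if i == j:
            continue
        a, b = proteins[i], proteins[j]
        if member_of.get(a) is not None and member_of.get(a) == member_of.get(b):
            continue
        pair = canonical_pair(a, b)
        if pair not in true_ppis:
            bg.add(pair)
    true_ppis |= bg
    return SyntheticTruth(
        proteins=proteins,
        complexes=ComplexSet(complexes),
        true_ppis=true_ppis,
        params=dict(
            n_proteins=n_proteins, n_complexes=n_complexes,
            size_range=size_range, within_p=within_p, between_p=between_p,
        ),
        seed=seed,
    )


def _complex_ontology(
    truth: SyntheticTruth, noise: NoiseSpec, rng: np.random.Generator
) -> tuple[OntologyDAG, set[str]]:
    """Three-level DAG per namespace: root -> slim terms -> leaves.

    BP and CC get one leaf per planted complex whose members are
    annotated with it with probability ``annotation_prob``; MF leaves
    are assigned at random (function tracks complexes only loosely in
    real data).  The slim set is the mid-level tier.
    """
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    slim: set[str] = set()
    n_slim = 5
    n_cx = len(truth.complexes)
    leaves: dict[str, list[str]] = {}
    for ns in ("BP", "CC", "MF"):
        root = f"{ns}:root"
        parents[root] = set()
        namespace[root] = ns
        for j in range(n_slim):
            s = f"{ns}:slim{j}"
            parents[s] = {root}
            namespace[s] = ns
            slim.add(s)
        n_leaves = n_cx if ns != "MF" else n_slim * 2
        leaves[ns] = []
        for i in range(n_leaves):
            t = f"{ns}:leaf{i:02d}"
            parents[t] = {f"{ns}:slim{i % n_slim}"}
            namespace[t] = ns
            leaves[ns].append(t)
    annotations: dict[str, set[str]] = {}
    member_of: dict[str, int] = {}
    for ci, c in enumerate(truth.complexes):
        for p in c:
            member_of[p] = ci
    for p in truth.proteins:
        ann: set[str] = set()
        ci = member_of.get(p)
        for ns in ("BP", "CC"):
            if ci is not None and rng.random() < noise.annotation_prob:
                ann.add(leaves[ns][ci])
            elif rng.random() < noise.background_annotation_prob:
                ann.add(leaves[ns][rng.integers(len(leaves[ns]))])
        if rng.random() < noise.background_annotation_prob:
            ann.add(leaves["MF"][rng.integers(len(leaves["MF"]))])
        if ann:
            annotations[p] = ann
    dag = OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)
    return dag, slim


def _score_column(
    truth: SyntheticTruth, noise: NoiseSpec, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    col: dict[tuple[str, str], float] = {}
    trues = sorted(truth.true_ppis)
    n_prot = len(truth.proteins)
    for pair in trues:
        if rng.random() < noise.score_true_coverage:
            col[pair] = max(0.0, noise.score_true_mean + rng.normal(0, noise.score_sd))
    n_false = int(noise.score_false_ratio * len(trues))
    added = 0
    while added < n_false:
        i, j = rng.integers(0, n_prot, size=2)
        if i == j:
            continue
        pair = canonical_pair(truth.proteins[i], truth.proteins[j])
        if pair in truth.true_ppis or pair in col:
            continue
        col[pair] = max(0.0, noise.score_false_mean + rng.normal(0, noise.score_sd))
        added += 1
    return col


def generate_evidence(
    truth: SyntheticTruth, noise: NoiseSpec | None = None, seed: int = 1
) -> EvidenceStore:
    """Emit the six evidence sources for a planted truth."""
    if noise is None:
        noise = NoiseSpec()
    rng = np.random.default_rng(seed)

    dag, slim = _complex_ontology(truth, noise, rng)

    # expression: shared latent profile per complex + member noise
    n_s = noise.n_samples
    profiles = {}
    member_of: dict[str, int] = {}
    latents = rng.normal(size=(len(truth.complexes), n_s))
    for ci, c in enumerate(truth.complexes):
        for p in c:
            member_of[p] = ci
    for p in truth.proteins:
        ci = member_of.get(p)
        if ci is None:
            profiles[p] = rng.normal(size=n_s)
        else:
            profiles[p] = latents[ci] + rng.normal(0, noise.expr_noise_sd, size=n_s)
    expr = pd.DataFrame.from_dict(profiles, orient="index")
    expr.columns = [f"S{j:03d}" for j in range(n_s)]
    expr = expr.sort_index()

    # domains + DDI: covered proteins get a generic domain; a true PPI
    # between covered proteins gets a dedicated interacting domain pair
    domains: dict[str, set[str]] = {}
    for i, p in enumerate(truth.proteins):
        if rng.random() < noise.domain_coverage:
            domains[p] = {f"D_generic{i % 40:02d}"}
    ddi: dict[frozenset[str], float] = {}
    for k, (a, b) in enumerate(sorted(truth.true_ppis)):
        if a in domains and b in domains and rng.random() < noise.domain_pair_prob:
            da, db = f"D_int{k}a", f"D_int{k}b"
            domains[a].add(da)
            domains[b].add(db)
            ddi[frozenset((da, db))] = float(rng.uniform(0.5, 1.0))

    score_columns = {"string": _score_column(truth, noise, rng)}
    for j in range(noise.apms_columns):
        score_columns[f"apms_{j + 1}"] = _score_column(truth, noise, rng)

    # observed network: true edges minus false negatives, plus spurious edges
    observed = nx.Graph()
    observed.add_nodes_from(truth.proteins)
    trues = sorted(truth.true_ppis)
    for a, b in trues:
        if rng.random() >= noise.observed_fn_rate:
            observed.add_edge(a, b)
    n_fp = int(noise.observed_fp_ratio * len(trues))
    added = 0
    while added < n_fp:
        i, j = rng.integers(0, len(truth.proteins), size=2)
        if i == j:
            continue
        pair = canonical_pair(truth.proteins[i], truth.proteins[j])
        if pair in truth.true_ppis or observed.has_edge(*pair):
            continue
        observed.add_edge(*pair)
        added += 1

    return EvidenceStore(
        ontology=dag,
        slim_terms=slim,
        expression=expr,
        domains=domains,
        ddi=ddi,
        score_columns=score_columns,
        observed_network=observed,
    )


def generate_pool(
    truth: SyntheticTruth,
    positive_fraction: float = 0.5,
    seed: int = 2,
) -> tuple[LabeledPool, set[tuple[str, str]]]:
    """Split the candidate-pair universe into labeled positives and an
    unlabeled pool.

    Positives are a uniform ``positive_fraction`` of the true PPIs;
    every other candidate pair is unlabeled.  Returns the pool plus the
    hidden positives (true PPIs left in the unlabeled pool), which are
    evaluation-only ground truth.
    """
    if not (0 < positive_fraction <= 1):
        raise ValueError("positive_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    trues = sorted(truth.true_ppis)
    n_pos = round(positive_fraction * len(trues))
    idx = rng.choice(len(trues), size=n_pos, replace=False)
    positives = {trues[i] for i in idx}
    hidden = set(trues) - positives
    if not hidden:
        raise ValueError(
            "positive_fraction=1 leaves no hidden positives; ranking "
            "evaluation would be degenerate"
        )
    unlabeled = {p for p in truth.candidate_pairs() if p not in positives}
    return LabeledPool(positives=positives, unlabeled=unlabeled), hidden


def strong_signal_universe(seed: int = 0):
    """The default study conditions: desk-scale universe with planted
    complexes and moderately noisy evidence.  Returns
    (truth, evidence store, labeled pool, hidden positives)."""
    ss = np.random.SeedSequence(seed).generate_state(3)
    truth = generate_truth(seed=int(ss[0] % (2**31)))
    store = generate_evidence(truth, seed=int(ss[1] % (2**31)))
    pool, hidden = generate_pool(truth, seed=int(ss[2] % (2**31)))
    return truth, store, pool, hidden
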
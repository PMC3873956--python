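"""Evidence features: information-content GO similarity, slim overlap,
coexpression, DDI sums, neighbor overlap, assembly, the filtering
heuristics, and equal-frequency discretization.

Semantic-similarity and neighbor-overlap values are checked against
independent brute-force oracles on randomized fixtures.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import complexweaver as cw
from complexweaver.features import FeatureSchema, TermStats


# ---------------------------------------------------------------------------
# independent oracles


def brute_probability(dag: cw.OntologyDAG, term: str) -> float:
    """p(t) by naive counting: annotation events on t or any descendant
    over all events in the namespace."""
    ns = dag.namespace[term]
    closure = dag.descendants(term)
    events_on = sum(
        1 for ts in dag.annotations.values() for t in ts
        if t in closure and dag.namespace[t] == ns
    )
    total = sum(
        1 for ts in dag.annotations.values() for t in ts if dag.namespace[t] == ns
    )
    return events_on / total if events_on else 1.0 / (total + 1)


def brute_term_similarity(dag: cw.OntologyDAG, t1: str, t2: str) -> float:
    ns = dag.namespace[t1]
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if not common:
        return 0.0
    total = sum(
        1 for ts in dag.annotations.values() for t in ts if dag.namespace[t] == ns
    )
    if total <= 1:
        return 0.0
    best = max(-math.log(brute_probability(dag, t)) for t in common)
    return min(best / math.log(total), 1.0)


def random_dag(rng: np.random.Generator, n_terms: int) -> cw.OntologyDAG:
    """Random single-namespace DAG of <= n_terms terms with random
    multi-parent links and random annotations."""
    parents: dict[str, set[str]] = {"T00": set()}
    namespace = {"T00": "BP"}
    for i in range(1, n_terms):
        t = f"T{i:02d}"
        existing = sorted(parents)
        k = int(rng.integers(1, min(3, len(existing)) + 1))
        idx = rng.choice(len(existing), size=k, replace=False)
        parents[t] = {existing[j] for j in idx}
        namespace[t] = "BP"
    proteins = [f"P{i}" for i in range(int(rng.integers(3, 10)))]
    terms = sorted(parents)
    annotations = {}
    for p in proteins:
        k = int(rng.integers(1, 4))
        idx = rng.choice(len(terms), size=k, replace=False)
        annotations[p] = {terms[j] for j in idx}
    return cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)


# ---------------------------------------------------------------------------
# term probability / similarity


class TestTermProbability:
    def test_namespace_root_has_probability_one(self, tiny_dag):
        assert cw.term_probability("root", tiny_dag, "BP") == pytest.approx(1.0)

    def test_hand_computed_closure_sum(self):
        # root -> {t1, t2}; direct counts t1=3, t2=2, root=0
        dag = cw.OntologyDAG(
            parents={"root": set(), "t1": {"root"}, "t2": {"root"}},
            namespace={"root": "BP", "t1": "BP", "t2": "BP"},
            annotations={
                "a": {"t1"}, "b": {"t1"}, "c": {"t1"}, "d": {"t2"}, "e": {"t2"},
            },
        )
        assert cw.term_probability("t1", dag, "BP") == pytest.approx(3 / 5)

    def test_leaf_annotated_once_in_100(self):
        parents = {"root": set(), "leaf": {"root"}, "bulk": {"root"}}
        namespace = {t: "BP" for t in parents}
        annotations = {"p0": {"leaf"}}
        annotations.update({f"q{i}": {"bulk"} for i in range(99)})
        dag = cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)
        assert cw.term_probability("leaf", dag, "BP") == pytest.approx(0.01)

    def test_monotone_non_decreasing_to_ancestors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(4, 30)))
            stats = TermStats(dag, "BP")
            for t in dag.terms:
                for parent in dag.parents[t]:
                    assert stats.p(parent) >= stats.p(t) - 1e-12
            for root in dag.roots("BP"):
                assert stats.p(root) == pytest.approx(1.0)


class TestTermSimilarity:
    def test_siblings_under_root_have_zero_similarity(self, tiny_dag):
        # only common ancestor of mid1 and mid2 is the root: -ln 1 = 0
        assert cw.term_similarity("mid1", "mid2", tiny_dag, "BP") == 0.0

    def test_self_similarity_of_rarest_leaf_is_one(self):
        parents = {"root": set(), "leaf": {"root"}, "bulk": {"root"}}
        namespace = {t: "BP" for t in parents}
        annotations = {"p0": {"leaf"}}
        annotations.update({f"q{i}": {"bulk"} for i in range(99)})
        dag = cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)
        # p(leaf)=0.01 in a corpus of 100: normalization cancels exactly
        assert cw.term_similarity("leaf", "leaf", dag, "BP") == pytest.approx(1.0)

    def test_common_ancestor_at_p_point_one_in_corpus_100(self):
        # MICA with p=0.1, corpus 100: ln(10)/ln(100) = 0.5
        parents = {
            "root": set(), "ca": {"root"}, "x": {"ca"}, "y": {"ca"},
            "bulk": {"root"},
        }
        namespace = {t: "BP" for t in parents}
        annotations = {f"a{i}": {"x"} for i in range(5)}
        annotations.update({f"b{i}": {"y"} for i in range(5)})
        annotations.update({f"q{i}": {"bulk"} for i in range(90)})
        dag = cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)
        assert cw.term_probability("ca", dag, "BP") == pytest.approx(0.1)
        assert cw.term_similarity("x", "y", dag, "BP") == pytest.approx(0.5)

    def test_cross_namespace_comparison_rejected(self, tiny_dag):
        with pytest.raises(ValueError):
            cw.term_similarity("mid1", "mid2", tiny_dag, "CC")

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            dag = random_dag(rng, int(rng.integers(4, 30)))
            stats = TermStats(dag, "BP")
            terms = sorted(dag.terms)
            for _ in range(10):
                i, j = rng.integers(0, len(terms), size=2)
                t1, t2 = terms[i], terms[j]
                got = cw.term_similarity(t1, t2, dag, "BP", stats=stats)
                want = brute_term_similarity(dag, t1, t2)
                assert got == pytest.approx(want), (t1, t2)
                # symmetry
                assert got == pytest.approx(
                    cw.term_similarity(t2, t1, dag, "BP", stats=stats)
                )
                assert 0.0 <= got <= 1.0


class TestGeneGoSimilarity:
    def test_identical_rare_annotation_and_unannotated_absence(self):
        parents = {"root": set(), "leaf": {"root"}, "bulk": {"root"}}
        namespace = {t: "BP" for t in parents}
        annotations = {"p0": {"leaf"}, "p1": {"leaf"}}
        annotations.update({f"q{i}": {"bulk"} for i in range(98)})
        dag = cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations)
        # p(leaf)=2/100; IC ratio ln(50)/ln(100) < 1 — but a singleton
        # leaf hits the corpus minimum and normalizes to exactly 1
        annotations2 = dict(annotations)
        annotations2["p1"] = {"bulk"}
        dag2 = cw.OntologyDAG(parents=parents, namespace=namespace, annotations=annotations2)
        assert cw.gene_go_similarity("p0", "p0x", dag2, "BP") is None  # unannotated
        assert cw.gene_go_similarity("p0", "p1", dag, "BP") == pytest.approx(
            math.log(100 / 2) / math.log(100)
        )

    def test_root_related_annotations_give_zero(self, tiny_dag):
        assert cw.gene_go_similarity("A", "E", tiny_dag, "BP") == 0.0

    def test_equals_exhaustive_pairwise_max(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            dag = random_dag(rng, 12)
            prots = sorted(dag.annotations)
            a, b = prots[0], prots[-1]
            got = cw.gene_go_similarity(a, b, dag, "BP")
            want = max(
                brute_term_similarity(dag, x, y)
                for x in dag.annotations[a]
                for y in dag.annotations[b]
            )
            assert got == pytest.approx(want)


class TestGoSlimOverlap:
    def test_shared_non_root_slim_term(self, tiny_dag):
        # A and D both map up to mid1
        assert cw.goslim_overlap("A", "D", {"mid1", "mid2"}, "BP", tiny_dag) == 1

    def test_root_only_overlap_is_zero(self, tiny_dag):
        # slim set includes the root; A maps to {mid1}, E to {mid2}: the
        # shared root does not count
        assert cw.goslim_overlap("A", "E", {"root", "mid1", "mid2"}, "BP", tiny_dag) == 0

    def test_disjoint_slim_mappings_give_zero(self, tiny_dag):
        assert cw.goslim_overlap("A", "E", {"mid1", "mid2"}, "BP", tiny_dag) == 0

    def test_unannotated_protein_is_absent_not_zero(self, tiny_dag):
        assert cw.goslim_overlap("A", "ZZZ", {"mid1"}, "BP", tiny_dag) is None


class TestCoexpression:
    def test_identical_profiles(self):
        m = pd.DataFrame([[1.0, 2, 3, 4]] * 2, index=["g1", "g2"])
        assert cw.coexpression("g1", "g2", m) == pytest.approx(1.0)

    def test_negated_profile(self):
        m = pd.DataFrame([[1.0, 2, 3, 4], [-1.0, -2, -3, -4]], index=["g1", "g2"])
        assert cw.coexpression("g1", "g2", m) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        m = pd.DataFrame([[1.0, 2, 3, 4], [2.0, 4, 6, 9]], index=["g1", "g2"])
        # cov = 2.875, sd_x = sqrt(1.25), sd_y = sqrt(6.6875)
        r = cw.coexpression("g1", "g2", m)
        assert r == pytest.approx(2.875 / math.sqrt(1.25 * 6.6875), abs=1e-10)

    def test_too_few_common_samples_or_flat_profile_absent(self):
        m = pd.DataFrame(
            [[1.0, 2, np.nan, np.nan], [np.nan, 4, 6, 9], [5.0, 5, 5, 5]],
            index=["g1", "g2", "g3"],
        )
        assert cw.coexpression("g1", "g2", m) is None  # 1 common sample
        assert cw.coexpression("g3", "g2", m) is None  # zero variance


class TestDdiScore:
    TABLE = {frozenset({"d1", "d3"}): 0.4, frozenset({"d2"}): 0.5}
    DOMS = {"A": {"d1", "d2"}, "B": {"d2", "d3"}}

    def test_hand_sum_over_domain_pairs(self):
        # pairs (d1,d2)=0, (d1,d3)=0.4, (d2,d2)=0.5, (d2,d3)=0 -> 0.9
        assert cw.ddi_score("A", "B", self.DOMS, self.TABLE) == pytest.approx(0.9)

    def test_protein_without_domains_scores_zero(self):
        assert cw.ddi_score("A", "Z", self.DOMS, self.TABLE) == 0.0

    def test_linearity_and_symmetry_and_row_order(self):
        doubled = {k: 2 * v for k, v in self.TABLE.items()}
        assert cw.ddi_score("A", "B", self.DOMS, doubled) == pytest.approx(1.8)
        assert cw.ddi_score("B", "A", self.DOMS, self.TABLE) == pytest.approx(
            cw.ddi_score("A", "B", self.DOMS, self.TABLE)
        )


class TestCdDistance:
    def test_adjacent_with_identical_neighbor_sets(self):
        g = nx.complete_graph(["X", "Y", "A", "B"])
        assert cw.cd_distance_feature(g, "X", "Y") == pytest.approx(1.0)

    def test_hand_example_with_self_inclusion(self):
        g = nx.Graph()
        g.add_edges_from([("X", v) for v in "ABC"])
        g.add_edges_from([("Y", v) for v in "BCD"])
        # N*(X)={X,A,B,C}, N*(Y)={Y,B,C,D}: 2*2/(4+4) = 0.5
        assert cw.cd_distance_feature(g, "X", "Y") == pytest.approx(0.5)

    def test_disjoint_neighborhoods(self):
        g = nx.Graph()
        g.add_edges_from([("X", "A"), ("Y", "B")])
        assert cw.cd_distance_feature(g, "X", "Y") == 0.0

    def test_absent_when_node_missing(self):
        g = nx.Graph()
        g.add_edge("X", "A")
        assert cw.cd_distance_feature(g, "X", "Q") is None

    def test_matches_set_oracle_and_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            n = int(rng.integers(4, 50))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            nodes = sorted(g.nodes)
            i, j = rng.choice(len(nodes), size=2, replace=False)
            x, y = nodes[i], nodes[j]
            got = cw.cd_distance_feature(g, x, y)
            sx = set(g.neighbors(x)) | {x}
            sy = set(g.neighbors(y)) | {y}
            assert got == pytest.approx(2 * len(sx & sy) / (len(sx) + len(sy)))
            # invariance under relabeling
            mapping = {v: f"Z{v}" for v in g.nodes}
            h = nx.relabel_nodes(g, mapping)
            assert cw.cd_distance_feature(h, mapping[x], mapping[y]) == pytest.approx(got)


class TestAssembly:
    def test_schema_slot_counts(self):
        seven = tuple(["string"] + [f"apms_{i}" for i in range(1, 8)])
        assert len(FeatureSchema(score_columns=seven).names) == 17
        eight = seven + ("apms_8",)
        assert len(FeatureSchema(score_columns=eight).names) == 18

    def test_missing_table_is_configuration_error(self, small_universe):
        truth, store, pool, hidden = small_universe
        schema = FeatureSchema(score_columns=("nonexistent",))
        with pytest.raises(ValueError, match="nonexistent"):
            cw.assemble_features([("a", "b")], store, schema)

    def test_pair_absent_from_score_tables_still_gets_computed_slots(
        self, small_universe
    ):
        truth, store, pool, hidden = small_universe
        # two proteins from the universe that form no true PPI
        pair = sorted(set(truth.proteins) - truth.complexes.proteins())[:2]
        feats = cw.assemble_features([tuple(pair)], store)
        row = feats.iloc[0]
        assert np.isfinite(row["coexpression"])
        assert np.isfinite(row["cd_distance"])

    def test_deterministic_given_store(self, small_universe):
        truth, store, pool, hidden = small_universe
        pairs = sorted(pool.positives)[:50]
        a = cw.assemble_features(pairs, store)
        b = cw.assemble_features(pairs, store)
        pd.testing.assert_frame_equal(a, b)


class TestFilterHeuristics:
    def _row(self, **kw):
        cols = FeatureSchema(score_columns=("string", "apms_1")).names
        base = {c: np.nan for c in cols}
        base.update(kw)
        return pd.DataFrame([base], index=pd.MultiIndex.from_tuples([("A", "B")]))

    def test_weak_go_and_expression_only_pair_removed(self):
        f = self._row(
            go_type1_bp=0, go_type1_cc=0, go_type2_bp=0.001, go_type2_cc=0.0015,
            coexpression=0.3,
        )
        assert len(cw.filter_pairs(f)) == 0

    def test_any_other_evidence_retains(self):
        f = self._row(
            go_type1_bp=0, go_type1_cc=0, go_type2_bp=0.001, go_type2_cc=0.0015,
            coexpression=0.3, ddi=0.2,
        )
        assert list(cw.filter_pairs(f)) == [("A", "B")]

    def test_strong_coexpression_retains(self):
        f = self._row(
            go_type1_bp=0, go_type1_cc=0, go_type2_bp=0.0, go_type2_cc=0.0,
            coexpression=0.8,
        )
        assert list(cw.filter_pairs(f)) == [("A", "B")]

    def test_type1_hit_or_type2_above_threshold_retains(self):
        f1 = self._row(go_type1_bp=1, go_type2_bp=0.0, coexpression=0.0)
        assert len(cw.filter_pairs(f1)) == 1
        f2 = self._row(go_type2_cc=0.01, coexpression=0.0)
        assert len(cw.filter_pairs(f2)) == 1


class TestBinning:
    def test_hand_equal_frequency_split(self):
        f = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        spec = cw.fit_binning(f, 3)
        binary = cw.apply_binning(f, spec)
        assert spec.n_bins("x") == 3
        # value 3 falls in the middle bin
        assert binary.loc[2, ["x|bin0", "x|bin1", "x|bin2"]].tolist() == [0, 1, 0]
        # {1,2} | {3,4} | {5,6}
        assert binary["x|bin0"].sum() == 2
        assert binary["x|bin1"].sum() == 2
        assert binary["x|bin2"].sum() == 2

    def test_absent_value_sets_indicator_only(self):
        f = pd.DataFrame({"x": [1.0, 2, np.nan, 4, 5, 6]})
        binary = cw.apply_binning(f, cw.fit_binning(f, 2))
        row = binary.loc[2]
        assert row["x|absent"] == 1
        assert row.drop("x|absent").sum() == 0

    def test_constant_column_single_bin(self, caplog):
        f = pd.DataFrame({"x": [2.0] * 5})
        with caplog.at_level("WARNING"):
            spec = cw.fit_binning(f, 4)
        assert spec.n_bins("x") == 1
        binary = cw.apply_binning(f, spec)
        assert binary["x|bin0"].sum() == 5

    def test_one_active_column_per_feature_per_row(self):
        rng = np.random.default_rng(8)
        f = pd.DataFrame({
            "a": rng.normal(size=200),
            "b": np.where(rng.random(200) < 0.3, np.nan, rng.exponential(size=200)),
        })
        spec = cw.fit_binning(f, 5)
        binary = cw.apply_binning(f, spec)
        for feat in ("a", "b"):
            cols = [c for c in binary.columns if c.startswith(feat + "|")]
            assert (binary[cols].sum(axis=1) == 1).all()
        assert binary.shape[1] == spec.total_length

    def test_near_equal_occupancy_on_tie_free_data(self):
        rng = np.random.default_rng(9)
        f = pd.DataFrame({"x": rng.permutation(np.linspace(0, 1, 100))})
        spec = cw.fit_binning(f, 5)
        binary = cw.apply_binning(f, spec)
        counts = [binary[f"x|bin{j}"].sum() for j in range(5)]
        assert all(abs(c - 20) <= 1 for c in counts)
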
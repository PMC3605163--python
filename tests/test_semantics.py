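"""Information content, Resnik similarity, clustering, minimal subgraph, DOT."""

import math
import re

import numpy as np
import pytest

from gosig import (
    build_similarity_matrix,
    cluster_terms,
    compute_ic,
    emit_dot,
    minimal_subgraph,
    resnik,
)
from gosig.errors import ContractError
from gosig.semantics import ClusterAssignment, SimilarityMatrix


@pytest.fixture
def hand_ic(hand_dag):
    # direct annotation counts: root 2, A 2, B 0, C 2, D 2 -> total 8
    corpus = {"R": 2, "A": 2, "B": 0, "C": 2, "D": 2}
    return compute_ic(hand_dag, corpus, "BP")


class TestInformationContent:
    def test_root_ic_is_zero(self, hand_ic, hand_dag):
        assert hand_ic["R"] == 0.0

    def test_closed_form_on_hand_dag(self, hand_ic):
        # A subsumes A, C, D -> 6 of 8; C subsumes 2 of 8
        assert hand_ic["A"] == pytest.approx(-math.log(6 / 8))
        assert hand_ic["C"] == pytest.approx(-math.log(2 / 8))

    def test_manifest_enumeration_oracle(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        for term, expected in manifest["expected_ic"].items():
            if expected is None:
                assert term not in ic
            else:
                assert ic[term] == pytest.approx(expected, abs=1e-12)

    def test_monotone_along_every_edge(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        for child, parent in dag.graph.edges():
            if child in ic and parent in ic:
                assert ic[parent] <= ic[child] + 1e-12

    def test_zero_annotation_term_excluded(self, hand_dag):
        corpus = {"R": 1, "A": 1, "B": 0, "C": 0, "D": 0}
        ic = compute_ic(hand_dag, corpus, "BP")
        assert "B" not in ic and "C" not in ic  # subsume nothing
        assert "A" in ic


class TestResnik:
    def test_self_similarity_is_own_ic(self, hand_ic, hand_dag):
        for t in ("A", "C", "D"):
            assert resnik(hand_dag, hand_ic, t, t) == hand_ic[t]

    def test_siblings_sharing_only_root_score_zero(self, hand_dag):
        corpus = {"R": 0, "A": 4, "B": 2, "C": 1, "D": 1}
        ic = compute_ic(hand_dag, corpus, "BP")
        assert resnik(hand_dag, ic, "A", "B") == 0.0

    def test_most_informative_common_ancestor(self, hand_dag, hand_ic):
        # C and D share ancestors {A, R}; A is the informative one
        assert resnik(hand_dag, hand_ic, "C", "D") == hand_ic["A"]

    def test_mica_bound_over_all_pairs(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        terms = sorted(ic.values.keys())
        for t1 in terms:
            for t2 in terms:
                assert resnik(dag, ic, t1, t2) <= min(ic[t1], ic[t2]) + 1e-12


class TestSimilarityMatrix:
    def test_normalized_max_is_one_and_symmetric(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        terms = sorted(ic.values.keys())[:6]
        sim = build_similarity_matrix(dag, ic, terms)
        assert sim.normalized
        np.testing.assert_allclose(sim.values, sim.values.T)
        assert sim.values.max() == pytest.approx(1.0)
        assert sim.values.min() >= 0.0

    def test_entries_match_pairwise_resnik_calls(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        terms = sorted(ic.values.keys())[:5]
        sim = build_similarity_matrix(dag, ic, terms)
        raw = np.array([[resnik(dag, ic, a, b) for b in sim.terms] for a in sim.terms])
        np.testing.assert_allclose(sim.values, raw / raw.max())

    def test_degenerate_all_zero_returned_unnormalized(self, hand_dag):
        # A subsumes the whole corpus, so IC(A) = IC(R) = 0 -> all-zero matrix
        corpus = {"R": 0, "A": 0, "B": 0, "C": 4, "D": 4}
        ic = compute_ic(hand_dag, corpus, "BP")
        sim = build_similarity_matrix(hand_dag, ic, ["R", "A"])
        assert not sim.normalized
        assert np.all(sim.values == 0.0)

    def test_fewer_than_two_terms_is_error(self, hand_dag, hand_ic):
        with pytest.raises(ContractError):
            build_similarity_matrix(hand_dag, hand_ic, ["A"])


def _matrix(values, terms=None):
    values = np.asarray(values, dtype=float)
    terms = terms or [f"t{i}" for i in range(len(values))]
    return SimilarityMatrix(terms=terms, values=values, normalized=True)


class TestClustering:
    def test_all_similar_single_cluster(self):
        sim = _matrix(np.ones((4, 4)))
        assert cluster_terms(sim, 0.8).n_clusters == 1

    def test_two_blocks_separate_at_default_threshold(self):
        block = np.full((6, 6), 0.1)
        block[:3, :3] = 0.95
        block[3:, 3:] = 0.95
        np.fill_diagonal(block, 1.0)
        clusters = cluster_terms(_matrix(block), 0.8)
        assert clusters.n_clusters == 2
        labels = [clusters.labels[f"t{i}"] for i in range(6)]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_threshold_zero_single_cluster(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        assert cluster_terms(_matrix(vals), 0.0).n_clusters == 1

    def test_raising_threshold_never_decreases_cluster_count(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, (8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        sim = _matrix(vals)
        counts = [cluster_terms(sim, t).n_clusters for t in (0.0, 0.3, 0.6, 0.8, 0.95)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_invariant_under_prenormalization_rescale(self, toy_dag_bundle):
        dag, corpus, manifest = toy_dag_bundle
        ic = compute_ic(dag, corpus, manifest["domain"])
        terms = sorted(ic.values.keys())[:6]
        sim = build_similarity_matrix(dag, ic, terms)
        scaled = SimilarityMatrix(
            terms=sim.terms, values=(sim.values * 7.5) / (sim.values * 7.5).max(),
            normalized=True,
        )
        assert cluster_terms(sim, 0.8).labels == cluster_terms(scaled, 0.8).labels

    def test_labels_contiguous_positive(self):
        block = np.eye(5)
        clusters = cluster_terms(_matrix(block), 0.8)
        labels = set(clusters.labels.values())
        assert labels == set(range(1, len(labels) + 1))


class TestMinimalSubgraph:
    def test_single_term_path_to_root(self, hand_dag):
        nodes, edges = minimal_subgraph(hand_dag, ["C"])
        assert nodes == {"C", "A", "B", "R"}
        assert ("A", "C") in edges and ("R", "A") in edges

    def test_union_of_ancestor_paths_no_duplication(self, hand_dag):
        nodes, edges = minimal_subgraph(hand_dag, ["C", "D"])
        assert nodes == {"C", "D", "A", "B", "R"}

    def test_matches_brute_force_closure(self, toy_dag_bundle):
        dag, _, _ = toy_dag_bundle
        terms = sorted(dag.terms)[2:6]
        nodes, edges = minimal_subgraph(dag, terms)
        expected = set()
        for t in terms:
            expected |= {t} | dag.ancestors(t)
        assert nodes == expected
        for parent, child in edges:
            assert parent in dag.parents(child)

    def test_unknown_term_dropped(self, hand_dag):
        nodes, _ = minimal_subgraph(hand_dag, ["C", "GO:nope"])
        assert "GO:nope" not in nodes


class TestEmitDot:
    def test_two_clusters_two_fill_colors(self, hand_dag):
        nodes, edges = minimal_subgraph(hand_dag, ["C", "D"])
        clusters = ClusterAssignment({"C": 1, "D": 2}, 0.8)
        dot = emit_dot(nodes, edges, clusters, hand_dag)
        colors = set(re.findall(r'fillcolor="([^"]+)"', dot))
        assert len(colors) == 2

    def test_ancestor_only_nodes_uncolored(self, hand_dag):
        nodes, edges = minimal_subgraph(hand_dag, ["C"])
        dot = emit_dot(nodes, edges, ClusterAssignment({"C": 1}, 0.8), hand_dag)
        for line in dot.splitlines():
            if line.strip().startswith('"A"') or line.strip().startswith('"R"'):
                assert "fillcolor" not in line

    def test_output_is_well_formed_dot(self, toy_dag_bundle):
        dag, _, _ = toy_dag_bundle
        terms = sorted(dag.terms)[1:5]
        nodes, edges = minimal_subgraph(dag, terms)
        clusters = ClusterAssignment({t: i + 1 for i, t in enumerate(terms)}, 0.8)
        dot = emit_dot(nodes, edges, clusters, dag)
        assert dot.startswith("digraph ") and dot.rstrip().endswith("}")
        assert dot.count("{") == dot.count("}") == 1
        # every edge statement references declared nodes
        declared = set(re.findall(r'^\s*"([^"]+)" \[', dot, flags=re.M))
        for a, b in re.findall(r'"([^"]+)" -> "([^"]+)";', dot):
            assert a in declared and b in declared
        assert declared == nodes
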
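"""Similarity-network construction against exhaustive brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from lmflnc import (GeneAnnotationTable, disease_similarity_matrix,
                    fuse_similarities, gene_go_jaccard, gene_set_similarity,
                    lin_similarity, metabolite_similarity,
                    metabolite_similarity_matrix, term_frequency,
                    term_probability)
from lmflnc.similarity import TermDag, TermDagError
from lmflnc.synthetic import generate_toy_dag

from conftest import random_similarity

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_frequency(dag, t):
    """Sum of self counts over the descendant set, found by BFS on the
    parent->child graph (independent of the library's networkx call)."""
    seen = {t}
    frontier = [t]
    while frontier:
        node = frontier.pop()
        for child in dag.graph.successors(node):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return sum(dag.self_counts.get(s, 0) for s in seen)


def oracle_lin(dag, t1, t2):
    """Enumerate every common ancestor explicitly and take the best score."""
    n = oracle_frequency(dag, dag.root)
    p = {t: oracle_frequency(dag, t) / n for t in dag.graph}
    if t1 == t2:
        return 1.0
    if p[t1] >= 1.0 or p[t2] >= 1.0:
        return 0.0
    up1 = {t1} | nx.ancestors(dag.graph, t1)
    up2 = {t2} | nx.ancestors(dag.graph, t2)
    best = 0.0
    for t in up1 & up2:
        score = 2 * math.log(p[t]) / (math.log(p[t1]) + math.log(p[t2]))
        best = max(best, score)
    return best


def oracle_metabolite_similarity(m1, m2, table):
    """Literal double loop over both gene sets."""
    g1 = sorted(table.metabolite_genes[m1])
    g2 = sorted(table.metabolite_genes[m2])

    def jac(a, b):
        sa, sb = table.go_sets[a], table.go_sets[b]
        return len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0

    total = sum(max(jac(g, h) for h in g2) for g in g1)
    total += sum(max(jac(g, h) for h in g1) for g in g2)
    return total / (len(g1) + len(g2))


# ---------------------------------------------------------------------------
# term frequency / probability
# ---------------------------------------------------------------------------


def test_leaf_frequency_is_self_count(chain_dag):
    assert term_frequency(chain_dag, "b") == 1


def test_chain_root_frequency_sums_chain(chain_dag):
    assert term_frequency(chain_dag, "R") == 3


def test_diamond_counts_shared_child_once(diamond_dag):
    # c has two parents; descendant-set semantics count it once
    assert term_frequency(diamond_dag, "R") == 4
    assert term_frequency(diamond_dag, "R") == oracle_frequency(diamond_dag, "R")
    assert term_frequency(diamond_dag, "a") == 2


def test_frequency_matches_oracle_on_random_dags():
    for seed in range(5):
        dag = generate_toy_dag(depth=4, branching=2, seed=seed,
                               extra_parent_prob=0.5)
        for t in dag.graph:
            assert term_frequency(dag, t) == oracle_frequency(dag, t)


def test_probability_of_root_is_one(five_term_dag):
    assert term_probability(five_term_dag, "R") == 1.0


def test_chain_leaf_probability(chain_dag):
    assert term_probability(chain_dag, "b") == pytest.approx(1 / 3)


def test_probability_monotone_towards_root():
    for seed in range(5):
        dag = generate_toy_dag(depth=4, branching=2, seed=seed,
                               extra_parent_prob=0.3)
        for child, parent in ((c, p) for p in dag.graph
                              for c in dag.graph.successors(p)):
            assert (term_probability(dag, parent)
                    >= term_probability(dag, child) > 0.0)


def test_unknown_term_raises(chain_dag):
    with pytest.raises(KeyError):
        term_frequency(chain_dag, "nope")


def test_cyclic_hierarchy_rejected():
    with pytest.raises(TermDagError):
        TermDag.from_edges([("a", "R"), ("R", "a")], {"R": 1, "a": 1})


def test_zero_annotation_dag_rejected():
    dag = TermDag.from_edges([("a", "R")], {"R": 0, "a": 0})
    with pytest.raises(TermDagError):
        term_probability(dag, "a")


# ---------------------------------------------------------------------------
# Lin similarity
# ---------------------------------------------------------------------------


def test_self_similarity_is_one(five_term_dag):
    assert lin_similarity(five_term_dag, "x1", "x1") == 1.0


def test_root_only_common_ancestor_scores_zero(diamond_dag):
    assert lin_similarity(diamond_dag, "a", "b") == 0.0


def test_root_against_other_scores_zero(five_term_dag):
    assert lin_similarity(five_term_dag, "R", "x1") == 0.0
    assert lin_similarity(five_term_dag, "R", "R") == 1.0


def test_lin_matches_exhaustive_oracle(five_term_dag):
    terms = sorted(five_term_dag.graph)
    for t1 in terms:
        for t2 in terms:
            assert lin_similarity(five_term_dag, t1, t2) == pytest.approx(
                oracle_lin(five_term_dag, t1, t2), abs=1e-12)


def test_lin_symmetric_on_random_dags():
    dag = generate_toy_dag(depth=4, branching=2, seed=3,
                           extra_parent_prob=0.4)
    terms = sorted(dag.graph)[:8]
    for t1 in terms:
        for t2 in terms:
            assert lin_similarity(dag, t1, t2) == pytest.approx(
                lin_similarity(dag, t2, t1), abs=1e-15)


def test_disease_similarity_matrix_matches_pairwise(five_term_dag):
    diseases = ["x1", "x2", "y1", "x", "y"]
    net = disease_similarity_matrix(five_term_dag, diseases)
    for i, t1 in enumerate(diseases):
        for j, t2 in enumerate(diseases):
            assert net.matrix[i, j] == pytest.approx(
                oracle_lin(five_term_dag, t1, t2), abs=1e-12)
    assert np.allclose(np.diag(net.matrix), 1.0)
    assert np.max(np.abs(net.matrix - net.matrix.T)) < 1e-10


def test_disease_similarity_single_disease(five_term_dag):
    net = disease_similarity_matrix(five_term_dag, ["x1"])
    assert net.matrix.tolist() == [[1.0]]


def test_disease_similarity_unmapped_raises(five_term_dag):
    with pytest.raises(KeyError, match="bogus"):
        disease_similarity_matrix(five_term_dag, ["x1", "bogus"])


# ---------------------------------------------------------------------------
# gene / metabolite similarity
# ---------------------------------------------------------------------------


def test_jaccard_identical_and_disjoint(toy_annotations):
    assert gene_go_jaccard("g1", "g1", toy_annotations) == 1.0
    assert gene_go_jaccard("g1", "g4", toy_annotations) == 0.0


def test_jaccard_partial_overlap(toy_annotations):
    # {A,B} vs {B,C}: intersection 1, union 3
    assert gene_go_jaccard("g1", "g2", toy_annotations) == pytest.approx(1 / 3)


def test_jaccard_empty_union_is_zero(toy_annotations):
    assert gene_go_jaccard("g5", "g5", toy_annotations) == 0.0


def test_jaccard_unknown_gene_raises(toy_annotations):
    with pytest.raises(KeyError):
        gene_go_jaccard("g1", "gX", toy_annotations)


def test_gene_set_similarity_self_member(toy_annotations):
    assert gene_set_similarity("g1", {"g1", "g4"}, toy_annotations) == 1.0


def test_gene_set_similarity_exhaustive_max(toy_annotations):
    # g1 vs {g2, g3, g4}: max(1/3, 2/3, 0) = 2/3
    assert gene_set_similarity("g1", {"g2", "g3", "g4"},
                               toy_annotations) == pytest.approx(2 / 3)


def test_gene_set_similarity_empty_set_raises(toy_annotations):
    with pytest.raises(ValueError):
        gene_set_similarity("g1", set(), toy_annotations)


def test_metabolite_similarity_identical_gene_sets(toy_annotations):
    assert metabolite_similarity("m1", "m4", toy_annotations) == 1.0


def test_metabolite_similarity_disjoint_annotations(toy_annotations):
    # m3 = {g4} with GO {D}; no overlap with m1's genes
    assert metabolite_similarity("m1", "m3", toy_annotations) == 0.0


def test_metabolite_similarity_matches_double_loop_oracle(toy_annotations):
    for m1 in ("m1", "m2", "m3", "m4"):
        for m2 in ("m1", "m2", "m3", "m4"):
            assert metabolite_similarity(m1, m2, toy_annotations) == (
                pytest.approx(oracle_metabolite_similarity(m1, m2,
                                                           toy_annotations),
                              abs=1e-12))


def test_metabolite_similarity_exactly_symmetric(toy_annotations):
    for m1 in ("m1", "m2", "m3"):
        for m2 in ("m1", "m2", "m3"):
            assert (metabolite_similarity(m1, m2, toy_annotations)
                    == metabolite_similarity(m2, m1, toy_annotations))


def test_metabolite_without_genes_raises():
    table = GeneAnnotationTable({"g1": frozenset({"A"})},
                                {"m1": frozenset({"g1"}),
                                 "m2": frozenset()})
    with pytest.raises(ValueError, match="m2"):
        metabolite_similarity("m1", "m2", table)
    assert table.annotated_metabolites() == ["m1"]


def test_metabolite_similarity_matrix_valid(toy_annotations):
    net = metabolite_similarity_matrix(toy_annotations)
    assert net.node_ids == ["m1", "m2", "m3", "m4"]
    assert np.max(np.abs(net.matrix - net.matrix.T)) < 1e-10
    assert net.matrix.min() >= 0 and net.matrix.max() <= 1


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def test_fuse_single_network_is_identity(similarity_6):
    fused = fuse_similarities([similarity_6], [1.0])
    np.testing.assert_allclose(fused.matrix, similarity_6.matrix)


def test_fuse_identical_networks_unchanged(similarity_6):
    fused = fuse_similarities([similarity_6, similarity_6])
    np.testing.assert_allclose(fused.matrix, similarity_6.matrix)


def test_fuse_weighted_average_hand_computed():
    a = random_similarity(3, seed=1)
    b = random_similarity(3, seed=2)
    fused = fuse_similarities([a, b], [1.0, 3.0])
    np.testing.assert_allclose(fused.matrix, (a.matrix + 3 * b.matrix) / 4,
                               atol=1e-15)


def test_fuse_mismatched_nodes_raises(similarity_6):
    other = random_similarity(5, seed=0)
    with pytest.raises(ValueError):
        fuse_similarities([similarity_6, other])
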
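import numpy as np
import pytest

from lmflnc import GeneAnnotationTable, SimilarityNetwork, TermDag


@pytest.fixture
def diamond_dag():
    """Root R with children a, b; both are parents of c; all self-counts 1."""
    edges = [("a", "R"), ("b", "R"), ("c", "a"), ("c", "b")]
    return TermDag.from_edges(edges, {"R": 1, "a": 1, "b": 1, "c": 1})


@pytest.fixture
def chain_dag():
    """R <- a <- b with self-counts 1 each."""
    return TermDag.from_edges([("a", "R"), ("b", "a")],
                              {"R": 1, "a": 1, "b": 1})


@pytest.fixture
def five_term_dag():
    """Two branches under the root with a shared grandchild.

        R -> x -> x1, x2 ; R -> y -> y1 ; x2 also child of y.
    """
    edges = [("x", "R"), ("y", "R"), ("x1", "x"), ("x2", "x"),
             ("x2", "y"), ("y1", "y")]
    counts = {"R": 2, "x": 3, "y": 1, "x1": 4, "x2": 2, "y1": 5}
    return TermDag.from_edges(edges, counts)


@pytest.fixture
def toy_annotations():
    """Hand-written gene-GO and metabolite-gene tables."""
    go_sets = {
        "g1": frozenset({"A", "B"}),
        "g2": frozenset({"B", "C"}),
        "g3": frozenset({"A", "B", "C"}),
        "g4": frozenset({"D"}),
        "g5": frozenset(),
    }
    met_genes = {
        "m1": frozenset({"g1", "g2"}),
        "m2": frozenset({"g3"}),
        "m3": frozenset({"g4"}),
        "m4": frozenset({"g1", "g2"}),
    }
    return GeneAnnotationTable(go_sets, met_genes)


def random_similarity(n, seed, zero_diag=False, prefix="N"):
    """Random symmetric similarity matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 0.0 if zero_diag else 1.0)
    return SimilarityNetwork([f"{prefix}{i}" for i in range(n)], sym)


@pytest.fixture
def similarity_6():
    return random_similarity(6, seed=7)
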